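"""Voxel-grid geometry and the mask / dose container types.

Conventions used throughout the package:

* patient LPS axes: +x = patient-left, +y = patient-posterior,
  +z = patient-superior; all distances in millimetres;
* 0-based indices; voxel positions refer to voxel *centers*;
* axial slice ``k`` means all voxels with third index ``k``;
* masks and dose grids must share a :class:`GridGeometry` before any
  metric or DVH computation — resampling is always explicit
  (:func:`adaptrt.dosimetry.resample_dose`), never implicit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

#: absolute tolerance (mm) for geometry equality
GEOM_TOL_MM = 1e-6


class ValidationError(ValueError):
    """Input violates a documented precondition."""


class GeometryMismatchError(ValidationError):
    """Two grids that must coincide do not."""


class EmptyMaskError(ValidationError):
    """Operation undefined on an empty structure mask."""


class UndefinedMetricError(ValidationError):
    """Metric has no defined value for these inputs (e.g. both masks empty)."""


@dataclass(frozen=True)
class Point3:
    """A point in patient coordinates, millimetres."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for c in (self.x, self.y, self.z):
            if not np.isfinite(c):
                raise ValidationError(f"Point3 components must be finite, got {c!r}")

    def __iter__(self) -> Iterator[float]:
        yield self.x
        yield self.y
        yield self.z

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class GridGeometry:
    """Regular axis-aligned voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z); each component >= 1.
    spacing
        Voxel size in mm along (x, y, z); each component > 0.
    origin
        Position (mm, patient coordinates) of the *center* of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(s) for s in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValidationError("shape, spacing and origin must be length-3")
        if any(s < 1 for s in shape):
            raise ValidationError(f"all shape components must be >= 1, got {shape}")
        if any(s <= 0 or not np.isfinite(s) for s in spacing):
            raise ValidationError(f"all spacing components must be > 0, got {spacing}")
        if any(not np.isfinite(o) for o in origin):
            raise ValidationError(f"origin must be finite, got {origin}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    # -- derived quantities -------------------------------------------------
    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def approx_equal(self, other: "GridGeometry", tol: float = GEOM_TOL_MM) -> bool:
        if self.shape != other.shape:
            return False
        return all(
            abs(a - b) <= tol
            for a, b in zip(self.spacing + self.origin, other.spacing + other.origin)
        )

    def nearest_index(self, point: Point3) -> tuple[int, int, int]:
        """Index of the voxel whose center is nearest to ``point``."""
        idx = tuple(
            int(round((c - o) / s))
            for c, o, s in zip(point, self.origin, self.spacing)
        )
        if any(i < 0 or i >= n for i, n in zip(idx, self.shape)):
            raise IndexError(f"point {tuple(point)} maps outside grid {self.shape}")
        return idx


def voxel_center(geometry: GridGeometry, index: tuple[int, int, int]) -> Point3:
    """Patient-coordinate position (mm) of a voxel center.

    Raises ``IndexError`` for out-of-bounds indices (negative indices are
    rejected — they are almost always bugs in this context).
    """
    if len(index) != 3:
        raise IndexError(f"index must be length-3, got {index!r}")
    for i, n in zip(index, geometry.shape):
        if not (0 <= int(i) < n):
            raise IndexError(f"index {tuple(index)} out of bounds for shape {geometry.shape}")
    return Point3(*(o + i * s for o, i, s in zip(geometry.origin, index, geometry.spacing)))


@dataclass
class StructureMask:
    """Binary occupancy volume for one anatomical structure."""

    geometry: GridGeometry
    voxels: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.shape != self.geometry.shape:
            raise ValidationError(
                f"mask array shape {self.voxels.shape} != geometry shape {self.geometry.shape}"
            )
        if self.voxels.dtype != bool:
            self.voxels = self.voxels != 0

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.voxels))

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * self.geometry.voxel_volume_mm3 / 1000.0

    def indices(self) -> np.ndarray:
        """(N, 3) integer indices of true voxels."""
        return np.argwhere(self.voxels)

    def points_mm(self) -> np.ndarray:
        """(N, 3) mm coordinates of true-voxel centers."""
        idx = self.indices().astype(float)
        return np.asarray(self.geometry.origin) + idx * np.asarray(self.geometry.spacing)

    def with_voxels(self, voxels: np.ndarray, name: str | None = None) -> "StructureMask":
        return StructureMask(self.geometry, voxels, self.name if name is None else name)


@dataclass
class DoseGrid:
    """Scalar dose (Gy) on a grid, with the plan's prescription attached."""

    geometry: GridGeometry
    dose: np.ndarray
    prescription: float

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.geometry.shape:
            raise ValidationError(
                f"dose array shape {self.dose.shape} != geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.dose)):
            raise ValidationError("dose values must be finite")
        if np.any(self.dose < 0):
            raise ValidationError("dose values must be non-negative")
        if not (np.isfinite(self.prescription) and self.prescription > 0):
            raise ValidationError(f"prescription must be > 0 Gy, got {self.prescription!r}")


def mask_volume_cm3(mask: StructureMask) -> float:
    """Volume of a mask in cm^3 (voxel count x voxel volume)."""
    return mask.volume_cm3


def assert_same_geometry(a: GridGeometry | StructureMask | DoseGrid,
                         b: GridGeometry | StructureMask | DoseGrid,
                         tol: float = GEOM_TOL_MM) -> None:
    """Raise :class:`GeometryMismatchError` naming the first differing field."""
    ga = a if isinstance(a, GridGeometry) else a.geometry
    gb = b if isinstance(b, GridGeometry) else b.geometry
    if ga.shape != gb.shape:
        raise GeometryMismatchError(f"shape differs: {ga.shape} vs {gb.shape}")
    for fieldname in ("spacing", "origin"):
        va, vb = getattr(ga, fieldname), getattr(gb, fieldname)
        if any(abs(x - y) > tol for x, y in zip(va, vb)):
            raise GeometryMismatchError(f"{fieldname} differs: {va} vs {vb}")
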