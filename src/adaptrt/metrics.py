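"""Geometric agreement metrics between paired structure masks.

Four metrics quantify how far an automatic contour is from its manually
corrected counterpart:

* **DSC** — Dice similarity coefficient, ``2|A∩B| / (|A|+|B|)``, overlap
  in [0, 1];
* **ASD** — average surface distance (mm): directed nearest-surface
  distances pooled over both surfaces and averaged, weighted by surface
  point counts;
* **HD95** — 95 % Hausdorff distance (mm): the larger of the two directed
  95th-percentile surface distances (linear-interpolated percentile);
* **CD** — centroid deviation (mm): Euclidean distance between the two
  unweighted voxel-center centroids,
  ``sqrt((XA-XB)^2 + (YA-YB)^2 + (ZA-ZB)^2)``.

Surfaces are the centers of mask voxels with at least one face-adjacent
(6-connectivity) background or out-of-grid neighbour; all distances are
point-to-point between voxel centers with anisotropic spacing respected.
Empty inputs raise rather than returning sentinel values, so summary
statistics can never silently absorb degenerate cases.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .grids import (
    EmptyMaskError,
    Point3,
    StructureMask,
    UndefinedMetricError,
    assert_same_geometry,
)

log = logging.getLogger(__name__)


@dataclass
class MetricRecord:
    """All four agreement metrics for one evaluation region."""

    region: str
    asd_mm: float
    cd_mm: float
    dsc: float
    hd95_mm: float


@dataclass
class SurfacePointSet:
    """Centers (mm) of the boundary voxels of a mask."""

    points: np.ndarray  # (N, 3) mm


def surface_voxels(mask: StructureMask) -> np.ndarray:
    """Boolean array marking mask voxels with a 6-neighbour outside the mask.

    Out-of-grid counts as outside, so voxels on the grid edge are surface.
    """
    if mask.is_empty:
        raise EmptyMaskError(f"surface of empty mask {mask.name!r} is undefined")
    v = mask.voxels
    interior = np.ones_like(v)
    for axis in range(3):
        fwd = np.roll(v, 1, axis=axis)
        bwd = np.roll(v, -1, axis=axis)
        # rolled-in wrap values must read as outside
        sl = [slice(None)] * 3
        sl[axis] = 0
        fwd[tuple(sl)] = False
        sl[axis] = -1
        bwd[tuple(sl)] = False
        interior &= fwd & bwd
    return v & ~interior


def surface_points(mask: StructureMask) -> SurfacePointSet:
    """Surface-voxel centers in mm."""
    surf = surface_voxels(mask)
    idx = np.argwhere(surf).astype(float)
    pts = np.asarray(mask.geometry.origin) + idx * np.asarray(mask.geometry.spacing)
    return SurfacePointSet(points=pts)


def _check_pair(a: StructureMask, b: StructureMask) -> None:
    assert_same_geometry(a, b)
    if a.is_empty or b.is_empty:
        raise EmptyMaskError(
            f"metric undefined: empty mask in pair ({a.name!r}, {b.name!r})"
        )


def dsc(a: StructureMask, b: StructureMask) -> float:
    """Dice similarity coefficient by voxel counting."""
    assert_same_geometry(a, b)
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise UndefinedMetricError("DSC undefined when both masks are empty")
    inter = int(np.count_nonzero(a.voxels & b.voxels))
    return 2.0 * inter / (na + nb)


def _directed_distances(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Distance from each point in ``src`` to its nearest point in ``dst``."""
    tree = cKDTree(dst)
    d, _ = tree.query(src, k=1)
    return np.asarray(d, dtype=float)


def asd(a: StructureMask, b: StructureMask) -> float:
    """Symmetrized average surface distance, mm.

    Pools both directed sums and divides by the total surface point count
    (surface-count-weighted symmetrization).
    """
    _check_pair(a, b)
    sa = surface_points(a).points
    sb = surface_points(b).points
    d_ab = _directed_distances(sa, sb)
    d_ba = _directed_distances(sb, sa)
    return float((d_ab.sum() + d_ba.sum()) / (len(d_ab) + len(d_ba)))


def hd95(a: StructureMask, b: StructureMask) -> float:
    """95 % Hausdorff distance, mm: max of directed 95th percentiles."""
    _check_pair(a, b)
    sa = surface_points(a).points
    sb = surface_points(b).points
    d_ab = _directed_distances(sa, sb)
    d_ba = _directed_distances(sb, sa)
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


def centroid(mask: StructureMask) -> Point3:
    """Unweighted mean of true-voxel centers, mm."""
    if mask.is_empty:
        raise EmptyMaskError(f"centroid of empty mask {mask.name!r} is undefined")
    return Point3(*mask.points_mm().mean(axis=0))


def centroid_deviation(a: StructureMask, b: StructureMask) -> float:
    """Euclidean distance (mm) between the two mask centroids."""
    _check_pair(a, b)
    ca = centroid(a).as_array()
    cb = centroid(b).as_array()
    return float(np.sqrt(((ca - cb) ** 2).sum()))


def evaluate_pair(a: StructureMask, b: StructureMask, region: str | None = None) -> MetricRecord:
    """All four metrics for one auto/manual mask pair."""
    return MetricRecord(
        region=region if region is not None else (a.name or b.name),
        asd_mm=asd(a, b),
        cd_mm=centroid_deviation(a, b),
        dsc=dsc(a, b),
        hd95_mm=hd95(a, b),
    )


def evaluate_regions(auto: Mapping[str, StructureMask] | "object",
                     manual: Mapping[str, StructureMask] | "object") -> list[MetricRecord]:
    """One :class:`MetricRecord` per label common to both subregion sets.

    Accepts plain mappings or :class:`adaptrt.subdivision.SubregionSet`.
    Labels missing on one side, or empty on one side, are skipped with a
    logged warning; no common labels at all is an error.
    """
    auto_map = getattr(auto, "labels", auto)
    manual_map = getattr(manual, "labels", manual)
    common = [k for k in auto_map if k in manual_map]
    skipped = set(auto_map) ^ set(manual_map)
    for label in sorted(skipped):
        log.warning("region %r present on only one side; skipped", label)
    if not common:
        raise UndefinedMetricError("no common region labels to evaluate")
    records: list[MetricRecord] = []
    for label in common:
        ma, mm = auto_map[label], manual_map[label]
        if ma.is_empty or mm.is_empty:
            log.warning("region %r empty on one side; skipped", label)
            continue
        records.append(evaluate_pair(ma, mm, region=label))
    if not records:
        raise UndefinedMetricError("all common region labels were empty on one side")
    return records
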