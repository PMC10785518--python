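"""Anatomical subdivision of target volumes and margin morphology.

The nodal clinical target volume (CTV-N) is partitioned into up to 11
evaluation subregions using three axial landmark planes — the bifurcation
of the common iliac artery, the first appearance of the piriformis muscle,
and the first appearance of the femoral head — plus the sagittal body
midline:

* four z-bands numbered inferior→superior: N1 below the femoral-head
  plane, N2 femoral-head→piriformis, N3 piriformis→iliac-bifurcation,
  N4 above the iliac bifurcation;
* N1 is split left/right at the midline (2 parts);
* N2 and N3 are each split into quadrants: left/right at the midline and
  up/down at the axial mid-plane of that band's occupied z-extent
  (4 + 4 parts);
* N4 stays whole (1 part) — 11 parts in total.

Vaginal (CTV-V) and cervical (CTV-C) targets are split into upper and
lower halves at the mid-level of their occupied z-extent.

Tie-breaking is half-open and deterministic: a voxel center exactly on a
boundary plane belongs to the superior band / upper half, and a voxel
center exactly on the midline belongs to the patient-right side
(+x = patient-left).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .grids import (
    EmptyMaskError,
    StructureMask,
    ValidationError,
)

log = logging.getLogger(__name__)

#: canonical subregion names in inferior→superior, left-before-right order
CTVN_LABELS = (
    "CTV-N1_left", "CTV-N1_right",
    "CTV-N2_left-up", "CTV-N2_right-up", "CTV-N2_left-down", "CTV-N2_right-down",
    "CTV-N3_left-up", "CTV-N3_right-up", "CTV-N3_left-down", "CTV-N3_right-down",
    "CTV-N4",
)


@dataclass(frozen=True)
class LandmarkSet:
    """Axial landmark planes (mm, patient z) and sagittal midline (mm, x).

    Superior is larger z, so the iliac bifurcation is the most superior
    plane and the femoral head the most inferior.
    """

    z_iliac_bifurcation: float
    z_piriformis: float
    z_femoral_head: float
    midline_x: float

    def __post_init__(self) -> None:
        pairs = [
            ("z_iliac_bifurcation", self.z_iliac_bifurcation, "z_piriformis", self.z_piriformis),
            ("z_piriformis", self.z_piriformis, "z_femoral_head", self.z_femoral_head),
        ]
        for hi_name, hi, lo_name, lo in pairs:
            if not hi > lo:
                raise ValidationError(
                    f"landmark ordering violated: {hi_name} ({hi}) must be > {lo_name} ({lo})"
                )
        for v in (self.z_iliac_bifurcation, self.z_piriformis, self.z_femoral_head, self.midline_x):
            if not np.isfinite(v):
                raise ValidationError("landmark coordinates must be finite")

    def shifted(self, dz: float) -> "LandmarkSet":
        return LandmarkSet(
            self.z_iliac_bifurcation + dz,
            self.z_piriformis + dz,
            self.z_femoral_head + dz,
            self.midline_x,
        )


@dataclass
class SubregionSet:
    """Disjoint labeled partition of a source mask.

    Construction verifies the partition invariants: subregions pairwise
    disjoint and their union voxelwise equal to the source.
    """

    source: StructureMask
    labels: dict[str, StructureMask]

    def __post_init__(self) -> None:
        acc = np.zeros(self.source.geometry.shape, dtype=np.int32)
        for m in self.labels.values():
            acc += m.voxels
        if acc.max(initial=0) > 1:
            raise ValidationError("subregions overlap")
        if not np.array_equal(acc.astype(bool), self.source.voxels):
            raise ValidationError("subregion union does not equal the source mask")

    def __iter__(self):
        return iter(self.labels.items())


def _z_coords(mask: StructureMask) -> np.ndarray:
    return mask.geometry.axis_coords(2)


def _occupied_z_mid(voxels: np.ndarray, z: np.ndarray) -> float:
    """Midpoint of the occupied z-extent (mean of lowest and highest occupied levels)."""
    occupied = np.flatnonzero(voxels.any(axis=(0, 1)))
    return 0.5 * (z[occupied[0]] + z[occupied[-1]])


def split_ctvn(mask: StructureMask, landmarks: LandmarkSet,
               quadrant_axis: Literal["z", "y"] = "z") -> SubregionSet:
    """Partition CTV-N into up to 11 landmark-defined subregions.

    ``quadrant_axis`` selects the second split axis inside the N2/N3
    bands: ``"z"`` (default) gives superior/inferior quadrant halves,
    ``"y"`` gives anterior/posterior halves ("up" = anterior, the smaller
    y in a supine patient).

    Empty subregions are omitted with a logged warning; on a phantom whose
    nodal chains span all four bands all 11 labels are nonempty.
    """
    if mask.is_empty:
        raise EmptyMaskError("cannot subdivide an empty CTV-N mask")
    geom = mask.geometry
    z = _z_coords(mask)
    z_lo, z_hi = z[0], z[-1]
    for name in ("z_femoral_head", "z_piriformis", "z_iliac_bifurcation"):
        zv = getattr(landmarks, name)
        if not (z_lo <= zv <= z_hi):
            raise ValidationError(
                f"landmark {name}={zv} mm outside grid z-range [{z_lo}, {z_hi}] mm"
            )

    # band index per slice: 0=N1 .. 3=N4; boundary slice joins the superior band
    band_of_slice = np.searchsorted(
        [landmarks.z_femoral_head, landmarks.z_piriformis, landmarks.z_iliac_bifurcation],
        z, side="right",
    )
    x = geom.axis_coords(0)
    left_col = x > landmarks.midline_x  # exactly-on-midline -> right
    y = geom.axis_coords(1)

    labels: dict[str, StructureMask] = {}

    def add(name: str, voxels: np.ndarray) -> None:
        if voxels.any():
            labels[name] = StructureMask(geom, voxels, name=name)
        else:
            log.warning("subregion %r is empty; omitted", name)

    v = mask.voxels
    for band, base in enumerate(("CTV-N1", "CTV-N2", "CTV-N3", "CTV-N4")):
        in_band = v & (band_of_slice == band)[None, None, :]
        if not in_band.any():
            log.warning("band %s contains no voxels; its subregions are omitted", base)
            continue
        left = in_band & left_col[:, None, None]
        right = in_band & ~left_col[:, None, None]
        if band == 0:
            add(f"{base}_left", left)
            add(f"{base}_right", right)
        elif band in (1, 2):
            if quadrant_axis == "z":
                mid = _occupied_z_mid(in_band, z)
                up_sel = (z >= mid)[None, None, :]
            else:
                occ = np.flatnonzero(in_band.any(axis=(0, 2)))
                mid = 0.5 * (y[occ[0]] + y[occ[-1]])
                up_sel = (y < mid)[None, :, None]  # anterior = "up" for a supine patient
            for side_name, side in (("left", left), ("right", right)):
                add(f"{base}_{side_name}-up", side & up_sel)
                add(f"{base}_{side_name}-down", side & ~up_sel)
        else:
            add(base, in_band)
    return SubregionSet(source=mask, labels=labels)


def split_longitudinal(mask: StructureMask) -> SubregionSet:
    """Split a target into upper and lower halves of its occupied z-extent.

    Slices with voxel-center z strictly below the extent midpoint go to
    ``{name}_down``; slices at or above it go to ``{name}_up``.
    """
    if mask.is_empty:
        raise EmptyMaskError("cannot split an empty mask")
    z = _z_coords(mask)
    mid = _occupied_z_mid(mask.voxels, z)
    up_sel = (z >= mid)[None, None, :]
    name = mask.name or "structure"
    labels: dict[str, StructureMask] = {}
    for suffix, sel in (("up", up_sel), ("down", ~up_sel)):
        voxels = mask.voxels & sel
        if voxels.any():
            labels[f"{name}_{suffix}"] = StructureMask(mask.geometry, voxels, name=f"{name}_{suffix}")
        else:  # pragma: no cover - cannot happen for a nonempty mask
            log.warning("half %r is empty; omitted", suffix)
    return SubregionSet(source=mask, labels=labels)


def expand_margin(mask: StructureMask, margin: float) -> StructureMask:
    """Isotropic margin expansion (e.g. the 5 mm CTV-to-PTV margin).

    Returns every voxel whose center lies within Euclidean distance
    ``margin`` mm of some source voxel center, respecting anisotropic
    spacing. The result is always a superset of the source.
    """
    if margin < 0:
        raise ValidationError(f"margin must be >= 0 mm, got {margin}")
    if margin == 0 or mask.is_empty:
        return StructureMask(mask.geometry, mask.voxels.copy(), name=mask.name)
    dist = ndimage.distance_transform_edt(~mask.voxels, sampling=mask.geometry.spacing)
    return mask.with_voxels(dist <= margin + 1e-9)


def erode_margin(mask: StructureMask, margin: float) -> StructureMask:
    """Erosion dual of :func:`expand_margin`: complement → dilate → complement."""
    if margin < 0:
        raise ValidationError(f"margin must be >= 0 mm, got {margin}")
    if margin == 0:
        return StructureMask(mask.geometry, mask.voxels.copy(), name=mask.name)
    complement = mask.with_voxels(~mask.voxels)
    if complement.is_empty:
        raise ValidationError("cannot erode a mask that fills the whole grid")
    grown = expand_margin(complement, margin)
    return mask.with_voxels(~grown.voxels)
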