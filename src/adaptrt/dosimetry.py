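"""Cumulative DVH construction and dose-volume metrics.

Implements the dose metrics used for plan comparison: V100% (volume
receiving the full prescription), VxGy in percent or absolute cm^3,
Dmean, and Dq (minimum dose to the hottest q, with q in percent or cm^3).

Conventions (stated once, applied everywhere):

* dose comparisons use ``>=`` — a voxel exactly at the threshold counts
  as covered;
* a pure voxel-count model: no sub-voxel partial-volume weighting;
* Dq converts q to a voxel count with ceiling; q must be positive and at
  most the structure volume.
"""
from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .grids import (
    DoseGrid,
    EmptyMaskError,
    GridGeometry,
    StructureMask,
    ValidationError,
    assert_same_geometry,
)


@dataclass
class DVHRecord:
    """One dosimetric metric value for one ROI under one plan variant."""

    roi: str
    plan: str  # "A-Adapted" | "A-Scheduled" | "S-Adapted" | "S-Scheduled"
    metric: str  # e.g. "V40Gy_pct", "Dmean_Gy", "D2cm3_Gy", "V100_pct"
    value: float


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram: percent volume >= dose."""

    dose_edges: np.ndarray
    cum_volume_pct: np.ndarray

    def __post_init__(self) -> None:
        self.dose_edges = np.asarray(self.dose_edges, dtype=float)
        self.cum_volume_pct = np.asarray(self.cum_volume_pct, dtype=float)
        if np.any(np.diff(self.dose_edges) <= 0):
            raise ValidationError("dose_edges must be strictly increasing")
        if np.any(np.diff(self.cum_volume_pct) > 1e-12):
            raise ValidationError("cumulative DVH must be non-increasing")


#: per-ROI metric panels used for the standard plan-comparison tables
DEFAULT_METRIC_PANEL: dict[str, list[str]] = {
    "bladder": ["V40Gy_pct", "V30Gy_pct", "V20Gy_pct", "V10Gy_pct", "Dmean_Gy", "D50pct_Gy"],
    "rectum": ["V40Gy_pct", "V30Gy_pct", "V20Gy_pct", "V10Gy_pct", "Dmean_Gy", "D50pct_Gy"],
    "bone_marrow": ["V10Gy_pct", "D90pct_Gy", "Dmean_Gy"],
    "femur_head_left": ["V30Gy_pct", "D5pct_Gy", "Dmean_Gy"],
    "femur_head_right": ["V30Gy_pct", "D5pct_Gy", "Dmean_Gy"],
    "bowel": ["V40Gy_pct", "V30Gy_pct", "V20Gy_pct", "V10Gy_pct",
              "D2cm3_Gy", "V40Gy_cm3", "V47Gy_cm3"],
    # target coverage
    "CTV-N": ["V100_pct"], "CTV-V": ["V100_pct"], "CTV-U": ["V100_pct"], "CTV-C": ["V100_pct"],
    "PTV-N": ["V100_pct"], "PTV-V": ["V100_pct"], "PTV-U": ["V100_pct"], "PTV-C": ["V100_pct"],
}


def resample_dose(dose: DoseGrid, target: GridGeometry) -> DoseGrid:
    """Trilinear resampling of a dose grid onto a target geometry.

    Target voxel centers outside the source extent get 0 Gy with a
    warning; completely disjoint extents are an error.
    """
    src = dose.geometry
    if src.approx_equal(target):
        return DoseGrid(target, dose.dose.copy(), dose.prescription)
    for axis in range(3):
        s = src.axis_coords(axis)
        t = target.axis_coords(axis)
        if t[-1] < s[0] or t[0] > s[-1]:
            raise ValidationError(
                f"source and target extents are disjoint along axis {axis}"
            )
    interp = RegularGridInterpolator(
        tuple(src.axis_coords(a) for a in range(3)),
        dose.dose, method="linear", bounds_error=False, fill_value=0.0,
    )
    xs, ys, zs = np.meshgrid(*(target.axis_coords(a) for a in range(3)), indexing="ij")
    pts = np.stack([xs, ys, zs], axis=-1).reshape(-1, 3)
    inside = np.ones(len(pts), dtype=bool)
    for axis in range(3):
        s = src.axis_coords(axis)
        inside &= (pts[:, axis] >= s[0]) & (pts[:, axis] <= s[-1])
    if not inside.all():
        warnings.warn(
            f"{(~inside).sum()} target voxels outside the source dose extent set to 0 Gy",
            stacklevel=2,
        )
    values = interp(pts).reshape(target.shape)
    values = np.clip(values, 0.0, None)  # guard tiny negative fp noise
    return DoseGrid(target, values, dose.prescription)


def _mask_doses(dose: DoseGrid, mask: StructureMask) -> np.ndarray:
    assert_same_geometry(dose, mask)
    if mask.is_empty:
        raise EmptyMaskError(f"DVH undefined for empty mask {mask.name!r}")
    return dose.dose[mask.voxels]


def dvh_curve(dose: DoseGrid, mask: StructureMask, bin_width: float = 0.1) -> DVHCurve:
    """Cumulative DVH of the in-mask voxel doses (percent of mask volume)."""
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0 Gy")
    d = _mask_doses(dose, mask)
    edges = np.arange(0.0, d.max() + 2 * bin_width, bin_width)
    cum = 100.0 * (d[None, :] >= edges[:, None]).mean(axis=1)
    return DVHCurve(dose_edges=edges, cum_volume_pct=cum)


def v_dose(dose: DoseGrid, mask: StructureMask, threshold: float,
           mode: str = "percent") -> float:
    """Volume of the mask receiving at least ``threshold`` Gy.

    ``mode="percent"`` returns percent of the mask volume; ``mode="cm3"``
    returns absolute cm^3.
    """
    d = _mask_doses(dose, mask)
    covered = int(np.count_nonzero(d >= threshold))
    if mode == "percent":
        return 100.0 * covered / d.size
    if mode == "cm3":
        return covered * mask.geometry.voxel_volume_mm3 / 1000.0
    raise ValidationError(f"unknown mode {mode!r}; use 'percent' or 'cm3'")


def v100(dose: DoseGrid, mask: StructureMask) -> float:
    """Percent of the mask receiving at least 100 % of the prescription."""
    return v_dose(dose, mask, dose.prescription, mode="percent")


def d_volume(dose: DoseGrid, mask: StructureMask, q: float,
             unit: str = "percent") -> float:
    """Minimum dose (Gy) received by the hottest ``q`` of the structure.

    ``unit="percent"``: q percent of the mask volume; ``unit="cm3"``:
    absolute volume. The quantity is converted to a voxel count with
    ceiling; the in-mask doses are sorted descending and the value at
    that rank returned.
    """
    d = _mask_doses(dose, mask)
    n = d.size
    if unit == "percent":
        if not 0 < q <= 100:
            raise ValidationError(f"percent q must be in (0, 100], got {q}")
        q_vox = q / 100.0 * n
    elif unit == "cm3":
        vol = mask.volume_cm3
        if not 0 < q <= vol + 1e-12:
            raise ValidationError(f"q = {q} cm3 exceeds structure volume {vol:.3f} cm3")
        q_vox = q * 1000.0 / mask.geometry.voxel_volume_mm3
    else:
        raise ValidationError(f"unknown unit {unit!r}; use 'percent' or 'cm3'")
    rank = min(max(int(math.ceil(q_vox - 1e-9)), 1), n)
    return float(np.sort(d)[::-1][rank - 1])


def d_mean(dose: DoseGrid, mask: StructureMask) -> float:
    """Arithmetic mean of the in-mask voxel doses, Gy."""
    return float(_mask_doses(dose, mask).mean())


_METRIC_RE = re.compile(
    r"^(?:"
    r"(?P<v100>V100_pct)|"
    r"V(?P<vthr>\d+(?:\.\d+)?)Gy_(?P<vmode>pct|cm3)|"
    r"D(?P<dq>\d+(?:\.\d+)?)(?P<dunit>pct|cm3)_Gy|"
    r"(?P<dmean>Dmean_Gy)"
    r")$"
)


def compute_metric(dose: DoseGrid, mask: StructureMask, metric: str) -> float:
    """Evaluate one named dose metric (e.g. ``"V40Gy_pct"``, ``"D2cm3_Gy"``)."""
    m = _METRIC_RE.match(metric)
    if m is None:
        raise ValidationError(f"unknown dose metric name {metric!r}")
    if m.group("v100"):
        return v100(dose, mask)
    if m.group("dmean"):
        return d_mean(dose, mask)
    if m.group("vthr"):
        mode = "percent" if m.group("vmode") == "pct" else "cm3"
        return v_dose(dose, mask, float(m.group("vthr")), mode=mode)
    unit = "percent" if m.group("dunit") == "pct" else "cm3"
    return d_volume(dose, mask, float(m.group("dq")), unit=unit)


def evaluate_plan(dose: DoseGrid, structures: dict[str, StructureMask],
                  metric_spec: dict[str, list[str]] | None = None,
                  plan: str = "") -> list[DVHRecord]:
    """One :class:`DVHRecord` per (ROI, metric) in the panel.

    ``metric_spec`` maps ROI name to metric names; it defaults to
    :data:`DEFAULT_METRIC_PANEL` restricted to the ROIs present.
    """
    if metric_spec is None:
        metric_spec = {k: v for k, v in DEFAULT_METRIC_PANEL.items() if k in structures}
    records: list[DVHRecord] = []
    for roi, metric_names in metric_spec.items():
        if roi not in structures:
            raise ValidationError(f"ROI {roi!r} in metric spec but not in structure set")
        for metric in metric_names:
            value = compute_metric(dose, structures[roi], metric)
            records.append(DVHRecord(roi=roi, plan=plan, metric=metric, value=value))
    return records
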