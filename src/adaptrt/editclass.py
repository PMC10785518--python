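"""Quantitative four-level edit-magnitude rubric for auto-contours.

In the online adaptive workflow, physicians grade how much each automatic
contour had to be edited: *no* edits, *minor* (no more than 10 % of
slices need small changes), *moderate* (more than 10 % of slices need
small changes, or no more than 10 % need big changes), or *major*
(anything beyond, including structural deletions and recontours).

The physicians' "small vs big" slice judgment is replaced by a
transparent per-slice surrogate: a changed slice is *small* when its 2D
Dice is at least ``small_dsc_min`` and its 2D Hausdorff distance is at
most ``small_hd_max_mm``; otherwise *big*. A slice present in exactly
one of the two masks is always *big*. Both thresholds are configurable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .grids import StructureMask, ValidationError, assert_same_geometry

#: severity order used by the monotonicity property
SEVERITY_ORDER = ("no", "minor", "moderate", "major")

DEFAULT_SMALL_DSC_MIN = 0.90
DEFAULT_SMALL_HD_MAX_MM = 3.0


@dataclass
class SliceChange:
    """Change assessment for one axial slice occupied in either mask."""

    slice_index: int
    present_auto: bool
    present_manual: bool
    slice_dsc: float | None
    slice_hd_mm: float | None
    category: str  # "unchanged" | "small" | "big"


@dataclass
class EditClassification:
    """Structure-level edit magnitude derived from per-slice changes."""

    structure: str
    label: str  # "no" | "minor" | "moderate" | "major"
    n_slices: int = 0
    frac_small: float = 0.0
    frac_big: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in SEVERITY_ORDER:
            raise ValidationError(f"unknown edit label {self.label!r}")
        if self.frac_small + self.frac_big > 1 + 1e-12:
            raise ValidationError("frac_small + frac_big must be <= 1")


def _boundary_2d(sl: np.ndarray) -> np.ndarray:
    """4-connectivity boundary pixels of a 2D binary slice."""
    interior = np.ones_like(sl)
    for axis in range(2):
        fwd = np.roll(sl, 1, axis=axis)
        bwd = np.roll(sl, -1, axis=axis)
        idx = [slice(None)] * 2
        idx[axis] = 0
        fwd[tuple(idx)] = False
        idx[axis] = -1
        bwd[tuple(idx)] = False
        interior &= fwd & bwd
    return sl & ~interior


def _slice_hd_mm(a: np.ndarray, b: np.ndarray, spacing_xy: tuple[float, float]) -> float:
    """Exact 2D Hausdorff distance between boundary pixel centers, mm."""
    pa = np.argwhere(_boundary_2d(a)).astype(float) * np.asarray(spacing_xy)
    pb = np.argwhere(_boundary_2d(b)).astype(float) * np.asarray(spacing_xy)
    d = cdist(pa, pb)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def slice_changes(auto: StructureMask, manual: StructureMask,
                  small_dsc_min: float = DEFAULT_SMALL_DSC_MIN,
                  small_hd_max_mm: float = DEFAULT_SMALL_HD_MAX_MM) -> list[SliceChange]:
    """Per-slice change assessment over slices occupied in either mask."""
    assert_same_geometry(auto, manual)
    sx, sy, _ = auto.geometry.spacing
    occupied = np.flatnonzero(auto.voxels.any(axis=(0, 1)) | manual.voxels.any(axis=(0, 1)))
    changes: list[SliceChange] = []
    for k in occupied:
        a = auto.voxels[:, :, k]
        m = manual.voxels[:, :, k]
        pa, pm = bool(a.any()), bool(m.any())
        if np.array_equal(a, m):
            changes.append(SliceChange(int(k), pa, pm, 1.0, 0.0, "unchanged"))
            continue
        if not (pa and pm):
            changes.append(SliceChange(int(k), pa, pm, None, None, "big"))
            continue
        sdsc = 2.0 * np.count_nonzero(a & m) / (np.count_nonzero(a) + np.count_nonzero(m))
        shd = _slice_hd_mm(a, m, (sx, sy))
        category = "small" if (sdsc >= small_dsc_min and shd <= small_hd_max_mm) else "big"
        changes.append(SliceChange(int(k), pa, pm, float(sdsc), shd, category))
    return changes


def classify_edit(changes: Sequence[SliceChange], structure: str = "") -> EditClassification:
    """Apply the four-level rubric to a slice-change list.

    * *no*: every slice unchanged;
    * *minor*: no big changes and at most 10 % of slices small;
    * *moderate*: no big changes but more than 10 % small, or at most
      10 % of slices big;
    * *major*: everything else.
    """
    if not changes:
        raise ValidationError("cannot classify an empty slice-change list")
    n = len(changes)
    n_small = sum(c.category == "small" for c in changes)
    n_big = sum(c.category == "big" for c in changes)
    frac_small, frac_big = n_small / n, n_big / n
    if n_small == 0 and n_big == 0:
        label = "no"
    elif n_big == 0 and frac_small <= 0.10:
        label = "minor"
    elif (n_big == 0 and frac_small > 0.10) or (0 < frac_big <= 0.10):
        label = "moderate"
    else:
        label = "major"
    return EditClassification(structure=structure, label=label, n_slices=n,
                              frac_small=frac_small, frac_big=frac_big)


def tabulate_edits(classifications: Sequence[EditClassification],
                   groups: Mapping[str, str] | Callable[[str], str] | None = None,
                   ) -> pd.DataFrame:
    """Frequency table of edit labels per group.

    ``groups`` maps a structure name to its group (dict or callable);
    by default each structure is its own group. The output has one row
    per group with counts per label, the total, and the percent of
    fractions needing no or minor edits rounded to one decimal.
    """
    if groups is None:
        key = lambda s: s
    elif callable(groups):
        key = groups
    else:
        key = lambda s, _g=groups: _g.get(s, s)
    rows: dict[str, dict[str, int]] = {}
    for c in classifications:
        g = key(c.structure)
        rows.setdefault(g, {lab: 0 for lab in SEVERITY_ORDER})
        rows[g][c.label] += 1
    table = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=list(SEVERITY_ORDER)).fillna(0).astype(int)
    table["total"] = table.sum(axis=1)
    with np.errstate(invalid="ignore"):
        pct = 100.0 * (table["no"] + table["minor"]) / table["total"]
    table["no_or_minor_pct"] = pct.round(1).where(table["total"] > 0, 0.0)
    table.index.name = "group"
    return table
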