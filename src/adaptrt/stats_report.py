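"""Paired plan comparison and summary-table assembly.

Plan variants compared: the re-optimized plan of the day ("Adapted") vs
the reference plan recalculated on the day's anatomy ("Scheduled"), each
under automatic ("A-") or physician-supervised ("S-") contours.  The two
standard paired comparisons are

* **p1** — S-Adapted vs S-Scheduled (does daily re-optimization help?),
* **p2** — A-Adapted vs S-Adapted (what does skipping manual edits cost?),

tested with a two-sided paired t-test on per-fraction differences; each
fraction is treated as an independent observation.  Summaries are
"mean ± SD" with the sample (n-1) standard deviation.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dosimetry import DVHRecord
from .grids import ValidationError
from .metrics import MetricRecord

#: Region display order for the contouring-comparison summary table
TABLE1_REGION_ORDER = [
    "CTV-N1_left", "CTV-N1_right",
    "CTV-N2_left-up", "CTV-N2_right-up", "CTV-N2_left-down", "CTV-N2_right-down",
    "CTV-N3_left-up", "CTV-N3_right-up", "CTV-N3_left-down", "CTV-N3_right-down",
    "CTV-N4",
    "CTV-V_down", "CTV-V_up", "CTV-C_down", "CTV-C_up",
    "CTV-U", "CTV-V", "CTV-C", "CTV-N",
]

#: (label, plan_a, plan_b) for the two standard paired comparisons
PLAN_PAIRS = [
    ("p1", "S-Adapted", "S-Scheduled"),
    ("p2", "A-Adapted", "S-Adapted"),
]


class PairedTResult(NamedTuple):
    t_stat: float
    p_value: float
    undefined: bool  # True when every paired difference is exactly zero


@dataclass
class PairedComparison:
    """Summary of one paired plan comparison for one (ROI, metric)."""

    metric: str
    roi: str
    pair: str  # "p1" | "p2"
    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_stat: float
    p_value: float
    undefined: bool


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTResult:
    """Two-sided paired t-test on the differences ``x - y``.

    If every difference is exactly zero the test is undefined (flagged,
    not reported as p = 1 or p = 0). Nonzero constant differences give
    an infinite t and p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 2:
        raise ValidationError(f"paired t-test needs n >= 2, got n = {n}")
    d = x - y
    if np.all(d == 0):
        return PairedTResult(t_stat=math.nan, p_value=math.nan, undefined=True)
    if np.std(d, ddof=1) == 0:
        return PairedTResult(t_stat=math.copysign(math.inf, d.mean()), p_value=0.0,
                             undefined=False)
    res = sps.ttest_rel(x, y)
    return PairedTResult(t_stat=float(res.statistic), p_value=float(res.pvalue),
                         undefined=False)


def summarize(series: Sequence[float]) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation; sd = 0 warned for n = 1."""
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot summarize an empty series")
    if arr.size == 1:
        warnings.warn("n = 1: standard deviation reported as 0", stacklevel=2)
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1))


def format_mean_sd(mean: float, sd: float, decimals: int = 2) -> str:
    return f"{mean:.{decimals}f} ± {sd:.{decimals}f}"


def format_p(result: PairedTResult, alpha: float = 0.05) -> str:
    """Render a p-value in the report style: "< 0.05" below alpha,
    otherwise "= 0.xx"; undefined tests render as "undefined"."""
    if result.undefined:
        return "undefined"
    if result.p_value < alpha:
        return f"< {alpha:g}"
    return f"= {result.p_value:.2f}"


def build_table1(per_fraction_records: Sequence[Sequence[MetricRecord]]) -> pd.DataFrame:
    """Contouring-comparison summary: mean ± SD of each metric per region.

    Input is one list of :class:`MetricRecord` per fraction. Regions are
    ordered by :data:`TABLE1_REGION_ORDER` (unknown regions appended
    alphabetically); a per-region ``n`` column records how many fractions
    contributed.
    """
    pooled: dict[str, dict[str, list[float]]] = {}
    for fraction in per_fraction_records:
        for rec in fraction:
            slot = pooled.setdefault(rec.region, {"asd": [], "cd": [], "dsc": [], "hd95": []})
            slot["asd"].append(rec.asd_mm)
            slot["cd"].append(rec.cd_mm)
            slot["dsc"].append(rec.dsc)
            slot["hd95"].append(rec.hd95_mm)
    if not pooled:
        raise ValidationError("no metric records to summarize")
    known = [r for r in TABLE1_REGION_ORDER if r in pooled]
    extra = sorted(set(pooled) - set(TABLE1_REGION_ORDER))
    rows = []
    for region in known + extra:
        slot = pooled[region]
        rows.append({
            "Region": region,
            "ASD (mm)": format_mean_sd(*summarize(slot["asd"])),
            "Centroid deviation (mm)": format_mean_sd(*summarize(slot["cd"])),
            "DSC": format_mean_sd(*summarize(slot["dsc"])),
            "95% HD (mm)": format_mean_sd(*summarize(slot["hd95"])),
            "n": len(slot["asd"]),
        })
    return pd.DataFrame(rows).set_index("Region")


def compare_pair(values_a: Sequence[float], values_b: Sequence[float],
                 metric: str, roi: str, pair: str) -> PairedComparison:
    res = paired_t(values_a, values_b)
    mean_a, sd_a = summarize(values_a)
    mean_b, sd_b = summarize(values_b)
    return PairedComparison(metric=metric, roi=roi, pair=pair, n=len(values_a),
                            mean_a=mean_a, sd_a=sd_a, mean_b=mean_b, sd_b=sd_b,
                            t_stat=res.t_stat, p_value=res.p_value,
                            undefined=res.undefined)


def build_dose_tables(per_fraction_records: Sequence[Sequence[DVHRecord]],
                      plan_pairs: Sequence[tuple[str, str, str]] = tuple(PLAN_PAIRS),
                      ) -> pd.DataFrame:
    """Plan-comparison summary with mean ± SD per variant and p columns.

    Input is one list of :class:`DVHRecord` per fraction, covering all
    four plan variants. Rows missing a plan variant in some fraction are
    flagged ``incomplete`` instead of silently dropped.
    """
    # (roi, metric) -> plan -> per-fraction values
    series: dict[tuple[str, str], dict[str, list[float]]] = {}
    roi_order: list[str] = []
    n_fractions = len(per_fraction_records)
    for fraction in per_fraction_records:
        for rec in fraction:
            key = (rec.roi, rec.metric)
            if rec.roi not in roi_order:
                roi_order.append(rec.roi)
            series.setdefault(key, {})
            series[key].setdefault(rec.plan, []).append(rec.value)
    if not series:
        raise ValidationError("no DVH records to summarize")
    plans = ["A-Adapted", "A-Scheduled", "S-Adapted", "S-Scheduled"]
    rows = []
    for roi in roi_order:
        for (r, metric), by_plan in series.items():
            if r != roi:
                continue
            complete = all(len(by_plan.get(p, [])) == n_fractions for p in plans)
            row: dict[str, object] = {"ROI": roi, "Metric": metric,
                                      "incomplete": not complete}
            for p in plans:
                vals = by_plan.get(p, [])
                row[p] = format_mean_sd(*summarize(vals)) if vals else ""
            for pair_name, pa, pb in plan_pairs:
                va, vb = by_plan.get(pa, []), by_plan.get(pb, [])
                if len(va) >= 2 and len(va) == len(vb):
                    row[pair_name] = format_p(paired_t(va, vb))
                else:
                    row[pair_name] = ""
            rows.append(row)
    return pd.DataFrame(rows)
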