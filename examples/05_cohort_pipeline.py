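"""Full pipeline: simulate a cohort on disk, then compare contours and plans.

Equivalent to the CLI sequence

    adaptrt simulate --out cohort/ --seed 7 --cohort uterine --n-fractions 5
    adaptrt compare  --cohort cohort/ --out compare.csv
    adaptrt dose     --cohort cohort/ --out dose.csv

but driven through the library API. Outputs land in a temp directory.
"""
import tempfile
from pathlib import Path

from adaptrt.pipeline import RunConfig, compare_cohort, dose_cohort, simulate_cohort

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp) / "cohort"
    cfg = RunConfig(cohort="uterine", n_fractions=5, seed=7,
                    grid_shape=(64, 64, 48), grid_spacing=(3.0, 3.0, 3.0))
    simulate_cohort(cfg, out)
    print(f"simulated {cfg.n_fractions} fractions under {out}")

    _, contour_table = compare_cohort(out)
    print("\nContour agreement (mean ± SD over fractions), selected regions:")
    print(contour_table.loc[["CTV-N1_left", "CTV-C_down", "CTV-C_up", "CTV-U", "CTV-N"]]
          .to_string())

    _, dose_table = dose_cohort(out)
    print("\nPlan comparison (V100% rows):")
    cols = ["ROI", "Metric", "S-Adapted", "S-Scheduled", "p1", "p2"]
    print(dose_table[dose_table["Metric"] == "V100_pct"][cols].to_string(index=False))
    print("\np1: S-Adapted vs S-Scheduled; p2: A-Adapted vs S-Adapted "
          "(paired t-test over fractions)")
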