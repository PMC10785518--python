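# adaptrt

Contour-agreement evaluation and dosimetric plan comparison for daily
online adaptive radiotherapy (oART) of cervical cancer.

In iCBCT-guided oART, an automatic workflow segments the influencer
organs (bladder, rectum, bowel), propagates the clinical target volumes
(CTVs) onto the anatomy of the day, and re-optimizes the plan. A human
"adapter" then reviews and edits the automatic contours. This package
provides the quantitative machinery to ask *where* the automatic
contours need editing and *what* skipping those edits costs
dosimetrically:

* **Anatomical subdivision** — the nodal CTV (CTV-N) is partitioned
  into 11 subregions by three axial landmark planes (femoral head,
  piriformis, iliac bifurcation) and the body midline; vaginal (CTV-V)
  and cervical (CTV-C) targets are halved along their length, so
  agreement can be localized to clinically meaningful zones.
* **Four geometric agreement metrics** per region, for an automatic
  mask A vs its corrected version B:
  - Dice similarity coefficient, DSC = 2|A∩B| / (|A|+|B|);
  - average surface distance, ASD (mm), pooled over both boundaries;
  - 95 % Hausdorff distance, HD95 (mm), the larger directed 95th
    percentile of boundary distances;
  - centroid deviation, CD(A,B) = √((X_A−X_B)² + (Y_A−Y_B)² + (Z_A−Z_B)²) (mm).
* **Edit-magnitude rubric** — each structure is graded no / minor /
  moderate / major from the fraction of axial slices needing small or
  big changes (per-slice Dice/Hausdorff surrogate for the physician's
  judgment), and graded frequencies are tabulated per cohort.
* **DVH engine** — V100 %, VxGy (% and cm³), Dmean, Dq% and Dq cm³ on a
  voxel-count dose model, plus trilinear dose resampling.
* **Paired plan statistics** — mean ± SD per plan variant and two-sided
  paired t-tests for the two standard contrasts: adapted vs scheduled
  under supervised contours (p1), and automatic vs supervised adapted
  plans (p2).
* **Synthetic phantom cohorts** — a seeded pelvic phantom generator with
  known ground-truth deformations (translation, margin change, per-slice
  jitter) and conformal sigmoidal dose fields, so every stage is
  testable end to end without patient data.

## Worked example

`examples/01_geometric_metrics.py` builds a spherical target and a
translated (3, 4, 0) mm, 1 mm-dilated copy standing in for an
auto/manual contour pair:

```
DSC   = 0.694   (1.0 would be identical contours)
ASD   = 2.49 mm (average surface-to-surface distance)
95%HD = 5.39 mm (robust worst-case boundary disagreement)
CD    = 5.00 mm (distance between centroids; the injected shift was |(3,4,0)| = 5 mm)
```

The centroid deviation recovers the injected rigid shift exactly; the
overlap and surface metrics respond to both the shift and the margin
change. `examples/05_cohort_pipeline.py` runs the whole pipeline on a
simulated 5-fraction cohort; its contour table shows the uterus (CTV-U)
with by far the largest deviations — the generator gives it the largest
interfractional motion, mirroring where adapters must focus — and its
plan table shows the re-optimized plan covering the day's PTV far better
than the recalculated reference plan (PTV-U V100 %: 100.00 ± 0.00 vs
77.79 ± 10.51, p1 < 0.05).

The same workflow is available from a shell:

```bash
adaptrt simulate --out cohort/ --seed 7 --cohort uterine --n-fractions 5
adaptrt compare  --cohort cohort/ --out compare.csv
adaptrt dose     --cohort cohort/ --out dose.csv
adaptrt report   --in compare.csv --format md
```

## Scope and data

The package operates on binary structure masks and dose grids on
axis-aligned voxel grids (NIfTI-1 on disk, LPS patient axes, mm).
Conversion from DICOM RT-STRUCT / RT-DOSE is an external step. No
patient data is included or required; the synthetic module generates all
inputs. See `docs/methods.md` for the models, conventions and
limitations.
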