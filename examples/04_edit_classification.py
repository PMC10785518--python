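"""Grade how much an automatic contour needed editing, slice by slice.

The four-level rubric (no / minor / moderate / major edits) is driven by
the fraction of axial slices needing small or big changes; 'small' is
judged by per-slice Dice and Hausdorff thresholds. A small synthetic
cohort is graded and the label frequencies tabulated per structure.
"""
from adaptrt.editclass import classify_edit, slice_changes, tabulate_edits
from adaptrt.grids import GridGeometry
from adaptrt.synthetic import PhantomConfig, make_cohort

config = PhantomConfig(geometry=GridGeometry(shape=(64, 64, 48), spacing=(3, 3, 3)),
                       cohort="uterine")
fractions = make_cohort(config, 10, seed=1, with_dose=False)

classifications = []
for f in fractions:
    for name in ("CTV-N", "CTV-U", "CTV-C", "bladder", "rectum", "bowel"):
        changes = slice_changes(f.auto[name], f.manual[name])
        classifications.append(classify_edit(changes, structure=name))

groups = {"bladder": "influencers", "rectum": "influencers", "bowel": "influencers",
          "CTV-N": "CTV", "CTV-U": "CTV", "CTV-C": "CTV"}
table = tabulate_edits(classifications, groups=groups)
print(table.to_string())
print("\n'no_or_minor_pct' is the share of auto-contours a therapist could "
      "accept with at most light editing.")
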