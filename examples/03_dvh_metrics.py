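"""Dose-volume metrics for a synthetic plan on a phantom.

Builds a dose field conformal to the PTV and reads off the standard
plan-evaluation numbers: target V100%, and OAR VxGy / Dmean / D50%.
"""
from adaptrt.dosimetry import evaluate_plan
from adaptrt.synthetic import PhantomConfig, build_ptvs, make_dose, make_phantom
from adaptrt.grids import StructureMask
import numpy as np

config = PhantomConfig(cohort="uterine")
structures, _ = make_phantom(config)
ptvs = build_ptvs(structures)

union = np.zeros(config.geometry.shape, dtype=bool)
for ptv in ptvs.values():
    union |= ptv.voxels
target = StructureMask(config.geometry, union, name="PTV")

dose = make_dose(config.geometry, target, prescription=config.prescription,
                 falloff_mm=4.0)
panel = {"PTV-U": ["V100_pct"], "PTV-N": ["V100_pct"],
         "bladder": ["V40Gy_pct", "V30Gy_pct", "Dmean_Gy", "D50pct_Gy"],
         "rectum": ["V40Gy_pct", "Dmean_Gy"]}
records = evaluate_plan(dose, {**structures, **ptvs}, panel, plan="S-Adapted")
for r in records:
    print(f"{r.roi:10s} {r.metric:10s} = {r.value:7.2f}")
print(f"\n(prescription {config.prescription} Gy; V100 is the percent of the "
      "structure receiving the full prescription)")
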