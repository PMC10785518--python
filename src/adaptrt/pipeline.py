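"""End-to-end orchestration: simulate → subdivide → compare → dose → report.

These functions are the library face of the command-line interface: each
consumes a cohort directory written by :func:`adaptrt.synthetic.write_cohort`
(or by an external converter producing the same layout) and returns both
the per-fraction records and the summary table.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as artio
from .dosimetry import DEFAULT_METRIC_PANEL, DVHRecord, evaluate_plan
from .grids import GridGeometry, StructureMask, ValidationError
from .metrics import MetricRecord, evaluate_regions
from .stats_report import build_dose_tables, build_table1
from .subdivision import split_ctvn, split_longitudinal
from .synthetic import (
    CohortDeformationParams,
    PhantomConfig,
    build_ptvs,
    make_cohort,
    write_cohort,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a simulated-cohort analysis run."""

    cohort: str = "uterine"
    n_fractions: int = 10
    seed: int = 0
    grid_shape: tuple[int, int, int] = (128, 128, 80)
    grid_spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)
    with_dose: bool = True
    falloff_mm: float = 4.0
    small_dsc_min: float = 0.90
    small_hd_max_mm: float = 3.0
    deformation: CohortDeformationParams = field(default_factory=CohortDeformationParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(payload, dict):
            raise ValidationError(f"config {path} must be a mapping")
        deform = payload.pop("deformation", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**payload)
        if deform:
            cfg.deformation = CohortDeformationParams(**deform)
        for tup in ("grid_shape", "grid_spacing"):
            setattr(cfg, tup, tuple(getattr(cfg, tup)))
        return cfg


def simulate_cohort(config: RunConfig, out_dir: str | Path) -> list[Path]:
    """Generate a deterministic synthetic cohort on disk; returns manifests."""
    phantom = PhantomConfig(
        geometry=GridGeometry(shape=config.grid_shape, spacing=config.grid_spacing),
        cohort=config.cohort, seed=config.seed)
    fractions = make_cohort(phantom, config.n_fractions, config.deformation,
                            seed=config.seed, with_dose=config.with_dose,
                            falloff_mm=config.falloff_mm)
    return write_cohort(fractions, out_dir)


def _load_masks(root: Path, paths: dict[str, str]) -> dict[str, StructureMask]:
    return {name: artio.read_mask_volume(root / rel, name=name)
            for name, rel in paths.items()}


def iter_manifests(cohort_dir: str | Path) -> list[tuple[Path, artio.CaseManifest]]:
    cohort_dir = Path(cohort_dir)
    manifest_paths = sorted(cohort_dir.glob("*/manifest.yaml"))
    if not manifest_paths:
        raise FileNotFoundError(f"no fraction manifests found under {cohort_dir}")
    return [(p, artio.read_manifest(p)) for p in manifest_paths]


def evaluation_regions(structures: dict[str, StructureMask],
                       landmarks) -> dict[str, StructureMask]:
    """All evaluation regions for one structure set.

    The nodal CTV contributes its 11 landmark subregions, the
    vaginal/cervical targets their longitudinal halves, and every whole
    CTV (including CTV-U) is evaluated undivided as well.
    """
    regions: dict[str, StructureMask] = {}
    for name, mask in structures.items():
        if not name.startswith("CTV"):
            continue
        if name == "CTV-N":
            regions.update(split_ctvn(mask, landmarks).labels)
        elif name in ("CTV-V", "CTV-C"):
            regions.update(split_longitudinal(mask).labels)
        regions[name] = mask
    return regions


def compare_cohort(cohort_dir: str | Path,
                   ) -> tuple[list[list[MetricRecord]], pd.DataFrame]:
    """Geometric auto-vs-manual comparison over a cohort directory.

    Returns the per-fraction metric records and the mean ± SD summary
    table over all evaluation regions.
    """
    cohort_dir = Path(cohort_dir)
    per_fraction: list[list[MetricRecord]] = []
    for mpath, manifest in iter_manifests(cohort_dir):
        landmarks = artio.read_landmarks(cohort_dir / manifest.landmarks_path)
        auto = _load_masks(cohort_dir, manifest.auto_masks)
        manual = _load_masks(cohort_dir, manifest.manual_masks)
        auto_regions = evaluation_regions(auto, landmarks)
        manual_regions = evaluation_regions(manual, landmarks)
        per_fraction.append(evaluate_regions(auto_regions, manual_regions))
    return per_fraction, build_table1(per_fraction)


def dose_cohort(cohort_dir: str | Path,
                metric_panel: dict[str, list[str]] | None = None,
                ) -> tuple[list[list[DVHRecord]], pd.DataFrame]:
    """Dosimetric plan comparison over a cohort directory.

    All plan variants are evaluated on the manually corrected contours
    (plus their PTVs); the summary table carries the p1 (S-Adapted vs
    S-Scheduled) and p2 (A-Adapted vs S-Adapted) paired-test columns.
    """
    cohort_dir = Path(cohort_dir)
    per_fraction: list[list[DVHRecord]] = []
    for mpath, manifest in iter_manifests(cohort_dir):
        if not manifest.doses:
            raise ValidationError(f"manifest {mpath} lists no dose volumes")
        manual = _load_masks(cohort_dir, manifest.manual_masks)
        structures = dict(manual)
        structures.update(build_ptvs(manual))
        panel = metric_panel or {k: v for k, v in DEFAULT_METRIC_PANEL.items()
                                 if k in structures}
        records: list[DVHRecord] = []
        for plan, rel in sorted(manifest.doses.items()):
            dose = artio.read_dose_volume(cohort_dir / rel, manifest.prescription)
            records.extend(evaluate_plan(dose, structures, panel, plan=plan))
        per_fraction.append(records)
    return per_fraction, build_dose_tables(per_fraction)
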