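"""Seeded synthetic pelvic phantom cohorts with known ground truth.

No patient imaging ships with this package, so every pipeline stage is
exercised on a parametric phantom that mimics the pelvic structure
inventory of a cervical-cancer adaptive course: bilateral nodal chains
(CTV-N) spanning all four landmark bands, midline target structures
(uterus CTV-U, cervical CTV-C or vaginal CTV-V), influencer organs
(bladder, rectum, bowel) and secondary OARs (femoral heads, bone
marrow), all placed relative to the grid extent so the same recipe
scales from quick test grids to the default 128x128x80 grid at
2x2x3 mm.

Paired "automatic vs manually corrected" contours are emulated by
applying a known deformation — rigid translation, uniform margin
change, and smooth per-slice boundary jitter — to the phantom; the
deformation actually applied is retained so parameter-recovery tests
can compare measured metrics against injected truth. Synthetic dose
fields are sigmoidal functions of the signed distance to a target
surface, concentrated on the PTV of the plan's reference anatomy.
Everything is deterministic under a fixed seed.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.special import expit

from . import io as artio
from .grids import DoseGrid, GridGeometry, StructureMask, ValidationError
from .subdivision import LandmarkSet, erode_margin, expand_margin

#: CTV-to-PTV planning margins, mm (uniform 3D); the uterus gets the
#: wider margin because its interfractional motion is the largest.
DEFAULT_MARGINS_MM = {"CTV-U": 10.0}
DEFAULT_MARGIN_MM = 5.0

#: prescription per cohort, Gy
COHORT_PRESCRIPTION_GY = {"postoperative": 45.0, "uterine": 50.4}

DEFAULT_GEOMETRY = GridGeometry(shape=(128, 128, 80), spacing=(2.0, 2.0, 3.0))


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, cohort and structure shape parameters of one phantom.

    All placement parameters are fractions of the grid extent so a
    single recipe stays anatomically proportioned at any grid size;
    resolved sizes are in mm.
    """

    geometry: GridGeometry = DEFAULT_GEOMETRY
    cohort: str = "uterine"
    seed: int = 0
    # landmark planes as fractions of the z extent (inferior -> superior)
    femoral_head_frac: float = 0.25
    piriformis_frac: float = 0.50
    iliac_bifurcation_frac: float = 0.75
    # nodal chains
    nodal_offset_frac: float = 0.16     # lateral offset of each tube from midline
    nodal_radius_frac: float = 0.05     # tube radius, fraction of x extent
    nodal_z_span: tuple[float, float] = (0.15, 0.90)
    include_secondary_oars: bool = True

    def __post_init__(self) -> None:
        if self.cohort not in COHORT_PRESCRIPTION_GY:
            raise ValidationError(
                f"unknown cohort {self.cohort!r}; valid: {sorted(COHORT_PRESCRIPTION_GY)}"
            )

    @property
    def prescription(self) -> float:
        return COHORT_PRESCRIPTION_GY[self.cohort]


def _extent(geometry: GridGeometry) -> np.ndarray:
    return (np.asarray(geometry.shape) - 1) * np.asarray(geometry.spacing) \
        + np.asarray(geometry.origin)


def _coords(geometry: GridGeometry):
    x = geometry.axis_coords(0)[:, None, None]
    y = geometry.axis_coords(1)[None, :, None]
    z = geometry.axis_coords(2)[None, None, :]
    return x, y, z


def _ellipsoid(geometry, center, semi) -> np.ndarray:
    x, y, z = _coords(geometry)
    cx, cy, cz = center
    ax, ay, az = semi
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _z_cylinder(geometry, center_xy, radius, z_range) -> np.ndarray:
    x, y, z = _coords(geometry)
    cx, cy = center_xy
    return (((x - cx) ** 2 + (y - cy) ** 2) <= radius ** 2) \
        & (z >= z_range[0]) & (z <= z_range[1])


def make_phantom(config: PhantomConfig) -> tuple[dict[str, StructureMask], LandmarkSet]:
    """Deterministic phantom structure set plus its landmark file content.

    The nodal chains span all four landmark bands and are mirror
    symmetric about the midline, so the 11-part subdivision is fully
    populated; targets and influencer organs are pairwise disjoint and
    none touches the grid boundary.
    """
    geom = config.geometry
    if any(abs(o) > 1e-9 for o in geom.origin):
        raise ValidationError("phantom placement assumes a grid origin of (0, 0, 0)")
    ext = _extent(geom)
    ex, ey, ez = ext
    mid_x = 0.5 * ex

    landmarks = LandmarkSet(
        z_iliac_bifurcation=geom.origin[2] + config.iliac_bifurcation_frac * (ez - geom.origin[2]),
        z_piriformis=geom.origin[2] + config.piriformis_frac * (ez - geom.origin[2]),
        z_femoral_head=geom.origin[2] + config.femoral_head_frac * (ez - geom.origin[2]),
        midline_x=mid_x,
    )

    structures: dict[str, np.ndarray] = {}

    # bilateral nodal chains -> CTV-N
    off = config.nodal_offset_frac * ex
    r_tube = config.nodal_radius_frac * ex
    z_span = (config.nodal_z_span[0] * ez, config.nodal_z_span[1] * ez)
    left = _z_cylinder(geom, (mid_x + off, 0.512 * ey), r_tube, z_span)
    right = _z_cylinder(geom, (mid_x - off, 0.512 * ey), r_tube, z_span)
    structures["CTV-N"] = left | right

    if config.cohort == "uterine":
        structures["CTV-U"] = _ellipsoid(
            geom, (mid_x, 0.47 * ey, 0.63 * ez), (0.10 * ex, 0.08 * ey, 0.13 * ez))
        structures["CTV-C"] = _z_cylinder(
            geom, (mid_x, 0.47 * ey), 0.05 * ey, (0.36 * ez, 0.49 * ez))
    else:
        structures["CTV-V"] = _z_cylinder(
            geom, (mid_x, 0.47 * ey), 0.045 * ey, (0.36 * ez, 0.60 * ez))

    # influencer organs
    structures["bladder"] = _ellipsoid(
        geom, (mid_x, 0.28 * ey, 0.50 * ez), (0.11 * ex, 0.095 * ey, 0.12 * ez))
    structures["rectum"] = _ellipsoid(
        geom, (mid_x, 0.75 * ey, 0.45 * ez), (0.07 * ex, 0.07 * ey, 0.15 * ez))
    structures["bowel"] = _ellipsoid(
        geom, (mid_x, 0.43 * ey, 0.89 * ez), (0.10 * ex, 0.13 * ey, 0.09 * ez))

    if config.include_secondary_oars:
        r_fem = 0.07 * min(ex, ey)
        for name, side in (("femur_head_left", +1), ("femur_head_right", -1)):
            structures[name] = _ellipsoid(
                geom, (mid_x + side * 0.355 * ex, 0.59 * ey, 0.28 * ez),
                (r_fem, r_fem, r_fem))
        x, y, z = _coords(geom)
        structures["bone_marrow"] = (
            (x >= 0.25 * ex) & (x <= 0.75 * ex)
            & (y >= 0.85 * ey) & (y <= 0.93 * ey)
            & (z >= 0.25 * ez) & (z <= 0.85 * ez))

    masks = {name: StructureMask(geom, v, name=name) for name, v in structures.items()}

    # config validation: pairwise disjoint, nonempty, inside the grid
    names = sorted(masks)
    shell = np.zeros(geom.shape, dtype=bool)
    shell[[0, -1], :, :] = shell[:, [0, -1], :] = shell[:, :, [0, -1]] = True
    for i, a in enumerate(names):
        if masks[a].is_empty:
            raise ValidationError(f"phantom structure {a!r} is empty; grid too coarse")
        if (masks[a].voxels & shell).any():
            raise ValidationError(f"phantom structure {a!r} touches the grid boundary")
        for b in names[i + 1:]:
            if (masks[a].voxels & masks[b].voxels).any():
                raise ValidationError(f"phantom structures {a!r} and {b!r} overlap")
    return masks, landmarks


def build_ptvs(structures: dict[str, StructureMask],
               margins_mm: dict[str, float] | None = None) -> dict[str, StructureMask]:
    """Planning target volumes: each CTV expanded by its planning margin.

    5 mm uniform 3D margin by default; 10 mm for the more mobile CTV-U.
    """
    overrides = DEFAULT_MARGINS_MM if margins_mm is None else margins_mm
    ptvs: dict[str, StructureMask] = {}
    for name, mask in structures.items():
        if not name.startswith("CTV"):
            continue
        margin = overrides.get(name, DEFAULT_MARGIN_MM)
        ptv_name = name.replace("CTV", "PTV", 1)
        expanded = expand_margin(mask, margin)
        ptvs[ptv_name] = expanded.with_voxels(expanded.voxels, name=ptv_name)
    return ptvs


# ---------------------------------------------------------------------------
# Known-truth deformations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructureDeformation:
    """Deformation applied to one structure: translation + margin + jitter."""

    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    margin_mm: float = 0.0           # > 0 dilation, < 0 erosion
    jitter_amp_mm: float = 0.0       # std of the per-slice boundary displacement
    jitter_corr_slices: float = 3.0  # Gaussian correlation length across slices
    jitter_superior_ramp: float = 1.0  # amplitude multiplier at the most superior slice


@dataclass(frozen=True)
class DeformationSpec:
    """Per-structure deformations for one fraction, plus the jitter seed."""

    per_structure: dict[str, StructureDeformation] = field(default_factory=dict)
    seed: int = 0

    def to_jsonable(self) -> dict:
        return {
            "seed": self.seed,
            "per_structure": {
                name: dataclasses.asdict(d) for name, d in sorted(self.per_structure.items())
            },
        }


def _shift_int(voxels: np.ndarray, shift: tuple[int, int, int]) -> np.ndarray:
    """Integer-voxel translation with zero fill (no wrap-around)."""
    out = voxels
    for axis, s in enumerate(shift):
        if s == 0:
            continue
        shifted = np.zeros_like(out)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        if s > 0:
            dst[axis], src[axis] = slice(s, None), slice(None, -s)
        else:
            dst[axis], src[axis] = slice(None, s), slice(-s, None)
        shifted[tuple(dst)] = out[tuple(src)]
        out = shifted
    return out


def snapped_translation(translation_mm, spacing) -> tuple[np.ndarray, np.ndarray]:
    """Grid-snapped integer shift and its realized mm translation."""
    shift = np.array([int(round(t / s)) for t, s in zip(translation_mm, spacing)])
    return shift, shift * np.asarray(spacing)


def _jitter_slice(sl: np.ndarray, amount_mm: float, spacing_xy) -> np.ndarray:
    """Dilate (amount > 0) or erode (amount < 0) one 2D slice by |amount| mm."""
    if not sl.any():
        return sl
    if amount_mm > 0:
        dist = ndimage.distance_transform_edt(~sl, sampling=spacing_xy)
        return dist <= amount_mm + 1e-9
    dist = ndimage.distance_transform_edt(sl, sampling=spacing_xy)
    return dist > -amount_mm + 1e-9


def perturb(structures: dict[str, StructureMask],
            spec: DeformationSpec) -> dict[str, StructureMask]:
    """Apply a known deformation to each structure named in the spec.

    Order of operations per structure: grid-snapped rigid translation,
    then uniform margin change (dilation or its erosion dual), then
    seeded smooth per-slice boundary jitter. Structures not named in
    the spec pass through unchanged. A deformation that empties a
    structure is an error.
    """
    out: dict[str, StructureMask] = {}
    seedseq = np.random.SeedSequence(spec.seed)
    children = {name: child for name, child in
                zip(sorted(spec.per_structure), seedseq.spawn(len(spec.per_structure)))}
    for name, mask in structures.items():
        d = spec.per_structure.get(name)
        if d is None:
            out[name] = mask
            continue
        geom = mask.geometry
        shift, _ = snapped_translation(d.translation_mm, geom.spacing)
        voxels = _shift_int(mask.voxels, tuple(shift))
        moved = mask.with_voxels(voxels)
        if d.margin_mm > 0:
            moved = expand_margin(moved, d.margin_mm)
        elif d.margin_mm < 0:
            moved = erode_margin(moved, -d.margin_mm)
        voxels = moved.voxels.copy()
        if d.jitter_amp_mm > 0:
            rng = np.random.default_rng(children[name])
            nz = geom.shape[2]
            raw = ndimage.gaussian_filter1d(rng.standard_normal(nz),
                                            sigma=max(d.jitter_corr_slices, 1e-6))
            sd = raw.std()
            profile = raw * (d.jitter_amp_mm / sd) if sd > 0 else np.zeros(nz)
            occupied = np.flatnonzero(voxels.any(axis=(0, 1)))
            if occupied.size:
                lo, hi = occupied[0], occupied[-1]
                ramp = np.ones(nz)
                if hi > lo and d.jitter_superior_ramp != 1.0:
                    ramp[lo:hi + 1] = np.linspace(1.0, d.jitter_superior_ramp, hi - lo + 1)
                half_pixel = 0.5 * min(geom.spacing[0], geom.spacing[1])
                for k in occupied:
                    amount = profile[k] * ramp[k]
                    if abs(amount) >= half_pixel:
                        voxels[:, :, k] = _jitter_slice(
                            voxels[:, :, k], amount, geom.spacing[:2])
        if not voxels.any():
            raise ValidationError(f"deformation emptied structure {name!r}")
        out[name] = mask.with_voxels(voxels)
    return out


# ---------------------------------------------------------------------------
# Synthetic dose
# ---------------------------------------------------------------------------

def make_dose(geometry: GridGeometry, target: StructureMask, prescription: float,
              falloff_mm: float = 4.0) -> DoseGrid:
    """Sigmoidal dose field conformal to a target structure.

    dose = 1.05 x prescription x logistic(depth / falloff + 3), where
    depth is the signed distance (mm, positive inside) to the target
    surface. The interior plateau sits 5 % above the prescription and
    the +3 offset puts the surface itself at about the prescription, so
    for a falloff small relative to the target size at least 95 % of
    target voxels receive the full prescription; dose falls toward zero
    a few falloff lengths outside.
    """
    if falloff_mm <= 0:
        raise ValidationError(f"falloff_mm must be > 0, got {falloff_mm}")
    if target.is_empty:
        raise ValidationError("cannot build a dose field for an empty target")
    spacing = geometry.spacing
    inside = ndimage.distance_transform_edt(target.voxels, sampling=spacing)
    outside = ndimage.distance_transform_edt(~target.voxels, sampling=spacing)
    depth = inside - outside
    dose = 1.05 * prescription * expit(depth / falloff_mm + 3.0)
    return DoseGrid(geometry, dose, prescription=prescription)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortDeformationParams:
    """Distribution scales for the per-fraction deformations.

    Defaults encode the qualitative anatomy of the problem: the uterus
    moves most (its fundus can shift by centimetres between fractions),
    vaginal/cervical targets deform moderately and more near their
    superior end, nodal chains are nearly stable, and influencer organs
    change filling (margin) as well as position.
    """

    uterus_translation_sigma_mm: float = 6.0
    uterus_margin_sigma_mm: float = 1.5
    uterus_jitter_amp_mm: float = 2.0
    vaginal_translation_sigma_mm: float = 2.0
    vaginal_jitter_amp_mm: float = 1.0
    vaginal_superior_ramp: float = 3.0
    nodal_translation_sigma_mm: float = 0.8
    nodal_jitter_amp_mm: float = 0.8
    organ_translation_sigma_mm: float = 3.0
    organ_margin_sigma_mm: float = 1.5
    organ_jitter_amp_mm: float = 1.5


@dataclass
class SyntheticFraction:
    """One simulated treatment fraction with its ground truth attached."""

    case_id: str
    fraction_id: str
    cohort: str
    prescription: float
    auto: dict[str, StructureMask]
    manual: dict[str, StructureMask]
    doses: dict[str, DoseGrid]
    landmarks: LandmarkSet
    truth: DeformationSpec
    manifest: artio.CaseManifest | None = None


def _draw_spec(structures: dict[str, StructureMask], params: CohortDeformationParams,
               rng: np.random.Generator, seed: int) -> DeformationSpec:
    per: dict[str, StructureDeformation] = {}
    for name in sorted(structures):
        if name == "CTV-U":
            per[name] = StructureDeformation(
                translation_mm=tuple(rng.normal(0, params.uterus_translation_sigma_mm, 3)),
                margin_mm=float(np.clip(rng.normal(0, params.uterus_margin_sigma_mm), -2.5, 2.5)),
                jitter_amp_mm=params.uterus_jitter_amp_mm)
        elif name in ("CTV-V", "CTV-C"):
            per[name] = StructureDeformation(
                translation_mm=tuple(rng.normal(0, params.vaginal_translation_sigma_mm, 3)),
                jitter_amp_mm=params.vaginal_jitter_amp_mm,
                jitter_superior_ramp=params.vaginal_superior_ramp)
        elif name == "CTV-N":
            per[name] = StructureDeformation(
                translation_mm=tuple(rng.normal(0, params.nodal_translation_sigma_mm, 3)),
                jitter_amp_mm=params.nodal_jitter_amp_mm)
        elif name in ("bladder", "rectum", "bowel"):
            per[name] = StructureDeformation(
                translation_mm=tuple(rng.normal(0, params.organ_translation_sigma_mm, 3)),
                margin_mm=float(np.clip(rng.normal(0, params.organ_margin_sigma_mm), -2.5, 2.5)),
                jitter_amp_mm=params.organ_jitter_amp_mm)
        # femoral heads / bone marrow are treated as rigid (no deformation)
    return DeformationSpec(per_structure=per, seed=seed)


def make_cohort(config: PhantomConfig, n_fractions: int,
                params: CohortDeformationParams | None = None,
                seed: int = 0, with_dose: bool = True,
                falloff_mm: float = 4.0) -> list[SyntheticFraction]:
    """Simulate a cohort of fractions for one phantom patient.

    Per fraction: the automatic contours are the reference phantom, the
    manual (corrected) contours are the phantom under a freshly drawn
    deformation, and four dose fields stand in for the plan variants —
    S-Adapted conformal to the manual PTV, while A-Adapted, A-Scheduled
    and S-Scheduled are conformal to the reference (= automatic) PTV.
    Each plan gets an independent ~1 % output-factor perturbation so no
    two plans are numerically identical. The deformation actually
    applied is stored as ``truth``.
    """
    if n_fractions < 1:
        raise ValidationError("n_fractions must be >= 1")
    params = params or CohortDeformationParams()
    auto, landmarks = make_phantom(config)
    rx = config.prescription
    reference_ptv = _union_mask(build_ptvs(auto), "PTV")
    ref_dose = make_dose(config.geometry, reference_ptv, rx, falloff_mm) if with_dose else None

    root = np.random.SeedSequence([seed, config.seed])
    fractions: list[SyntheticFraction] = []
    for i, child in enumerate(root.spawn(n_fractions)):
        rng = np.random.default_rng(child)
        jitter_seed = int(rng.integers(0, 2 ** 31 - 1))
        spec = _draw_spec(auto, params, rng, seed=jitter_seed)
        manual = perturb(auto, spec)
        doses: dict[str, DoseGrid] = {}
        if with_dose:
            manual_ptv = _union_mask(build_ptvs(manual), "PTV")
            adapted = make_dose(config.geometry, manual_ptv, rx, falloff_mm)
            for plan, base in (("S-Adapted", adapted), ("S-Scheduled", ref_dose),
                               ("A-Adapted", ref_dose), ("A-Scheduled", ref_dose)):
                factor = float(np.clip(rng.normal(1.0, 0.01), 0.9, 1.1))
                doses[plan] = DoseGrid(config.geometry, base.dose * factor, prescription=rx)
        fractions.append(SyntheticFraction(
            case_id=f"phantom-{config.cohort}", fraction_id=f"fx{i:03d}",
            cohort=config.cohort, prescription=rx, auto=auto, manual=manual,
            doses=doses, landmarks=landmarks, truth=spec))
    return fractions


def _union_mask(masks: dict[str, StructureMask], name: str) -> StructureMask:
    items = list(masks.values())
    voxels = np.zeros(items[0].geometry.shape, dtype=bool)
    for m in items:
        voxels |= m.voxels
    return StructureMask(items[0].geometry, voxels, name=name)


def write_cohort(fractions: list[SyntheticFraction], out_dir: str | Path) -> list[Path]:
    """Write a cohort as a directory tree of NIfTI volumes + YAML manifests.

    Layout: one subdirectory per fraction with ``auto/``, ``manual/`` and
    ``dose/`` volumes plus ``manifest.yaml``; shared ``landmarks.yaml``
    and a ``truth.json`` with every applied deformation at the root.
    Returns the manifest paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artio.write_landmarks(fractions[0].landmarks, out_dir / "landmarks.yaml")
    truth = {}
    manifest_paths: list[Path] = []
    for fx in fractions:
        fdir = out_dir / fx.fraction_id
        (fdir / "auto").mkdir(parents=True, exist_ok=True)
        (fdir / "manual").mkdir(exist_ok=True)
        (fdir / "dose").mkdir(exist_ok=True)
        auto_paths, manual_paths, dose_paths = {}, {}, {}
        for name, mask in fx.auto.items():
            p = fdir / "auto" / f"{name}.nii.gz"
            artio.write_mask_volume(mask, p)
            auto_paths[name] = str(p.relative_to(out_dir))
        for name, mask in fx.manual.items():
            p = fdir / "manual" / f"{name}.nii.gz"
            artio.write_mask_volume(mask, p)
            manual_paths[name] = str(p.relative_to(out_dir))
        for plan, dose in fx.doses.items():
            p = fdir / "dose" / f"{plan}.nii.gz"
            artio.write_dose_volume(dose, p)
            dose_paths[plan] = str(p.relative_to(out_dir))
        manifest = artio.CaseManifest(
            case_id=fx.case_id, fraction_id=fx.fraction_id, cohort=fx.cohort,
            prescription=fx.prescription, auto_masks=auto_paths,
            manual_masks=manual_paths, doses=dose_paths,
            landmarks_path="landmarks.yaml")
        fx.manifest = manifest
        mpath = fdir / "manifest.yaml"
        artio.write_manifest(manifest, mpath)
        manifest_paths.append(mpath)
        truth[fx.fraction_id] = fx.truth.to_jsonable()
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return manifest_paths
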