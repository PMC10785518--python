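"""Reading and writing masks, dose grids, landmarks, manifests, reports.

Volumes travel as NIfTI-1 with an axis-aligned affine: masks as unsigned
8-bit, dose as 32-bit float. The affine diagonal carries the voxel
spacing and the translation column the center of voxel (0, 0, 0); the
package's own patient axes (+x left, +y posterior, +z superior) map
directly onto the array axes, and rotated or oblique affines are
rejected rather than silently resampled. Landmarks and case manifests
are YAML; reports are CSV. Conversion from treatment-planning exports
(DICOM RT-STRUCT / RT-DOSE) is an external, documented step.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml

from .dosimetry import DVHRecord
from .grids import DoseGrid, GridGeometry, StructureMask, ValidationError
from .metrics import MetricRecord
from .subdivision import LandmarkSet

#: structure inventories expected per cohort
COHORT_STRUCTURES = {
    "postoperative": ("CTV-N", "CTV-V", "bladder", "rectum", "bowel"),
    "uterine": ("CTV-N", "CTV-U", "CTV-C", "bladder", "rectum", "bowel"),
}


@dataclass
class CaseManifest:
    """Locations and context of one treatment fraction on disk.

    ``auto_masks`` / ``manual_masks`` map structure name to a NIfTI path;
    ``doses`` maps plan variant ("S-Adapted", "S-Scheduled", and
    optionally "A-Adapted", "A-Scheduled") to a NIfTI path.
    """

    case_id: str
    fraction_id: str
    cohort: str  # "postoperative" | "uterine"
    prescription: float
    auto_masks: dict[str, str]
    manual_masks: dict[str, str]
    doses: dict[str, str] = field(default_factory=dict)
    landmarks_path: str = ""

    def __post_init__(self) -> None:
        if self.cohort not in COHORT_STRUCTURES:
            raise ValidationError(
                f"unknown cohort {self.cohort!r}; valid: {sorted(COHORT_STRUCTURES)}"
            )
        expected = COHORT_STRUCTURES[self.cohort]
        for role, masks in (("auto", self.auto_masks), ("manual", self.manual_masks)):
            missing = [s for s in expected if s.startswith("CTV") and s not in masks]
            if missing:
                raise ValidationError(
                    f"{role} mask set missing expected structures {missing} "
                    f"for cohort {self.cohort!r}"
                )


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def _affine_for(geometry: GridGeometry) -> np.ndarray:
    aff = np.diag(list(geometry.spacing) + [1.0])
    aff[:3, 3] = geometry.origin
    return aff


def _geometry_from(img: "nib.Nifti1Image") -> GridGeometry:
    aff = img.affine
    rot = aff[:3, :3]
    if np.any(np.abs(rot - np.diag(np.diag(rot))) > 1e-6) or np.any(np.diag(rot) <= 0):
        raise ValidationError(
            "unsupported orientation: affine must be axis-aligned with positive spacing"
        )
    return GridGeometry(shape=tuple(int(s) for s in img.shape[:3]),
                        spacing=tuple(float(d) for d in np.diag(rot)),
                        origin=tuple(float(t) for t in aff[:3, 3]))


def write_mask_volume(mask: StructureMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine_for(mask.geometry))
    nib.save(img, str(path))


def read_mask_volume(path: str | Path, name: str = "") -> StructureMask:
    """Load a binary mask; any nonzero voxel maps to true."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValidationError(f"expected a 3D volume, got shape {img.shape} in {path}")
    geometry = _geometry_from(img)
    data = np.asanyarray(img.dataobj)
    return StructureMask(geometry, data != 0, name=name or path.stem.replace(".nii", ""))


def write_dose_volume(dose: DoseGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(dose.dose.astype(np.float32), _affine_for(dose.geometry))
    nib.save(img, str(path))


def read_dose_volume(path: str | Path, prescription: float) -> DoseGrid:
    """Load a dose grid (Gy) and attach the plan prescription."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValidationError(f"expected a 3D volume, got shape {img.shape} in {path}")
    geometry = _geometry_from(img)
    data = np.asanyarray(img.dataobj).astype(float)
    if np.any(data < 0):
        raise ValidationError(f"negative dose values in {path}")
    return DoseGrid(geometry, data, prescription=prescription)


# ---------------------------------------------------------------------------
# Landmarks and manifests (YAML)
# ---------------------------------------------------------------------------

_LANDMARK_KEYS = ("z_iliac_bifurcation", "z_piriformis", "z_femoral_head", "midline_x")


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    payload = {k: float(getattr(landmarks, k)) for k in _LANDMARK_KEYS}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Load the three axial boundary levels and the body midline."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    payload = yaml.safe_load(path.read_text())
    if not isinstance(payload, dict):
        raise ValidationError(f"landmark file {path} must be a mapping")
    missing = [k for k in _LANDMARK_KEYS if k not in payload]
    if missing:
        raise ValidationError(f"landmark file {path} missing keys {missing}")
    return LandmarkSet(**{k: float(payload[k]) for k in _LANDMARK_KEYS})


def write_manifest(manifest: CaseManifest, path: str | Path) -> None:
    payload = {
        "case_id": manifest.case_id,
        "fraction_id": manifest.fraction_id,
        "cohort": manifest.cohort,
        "prescription": float(manifest.prescription),
        "auto_masks": dict(manifest.auto_masks),
        "manual_masks": dict(manifest.manual_masks),
        "doses": dict(manifest.doses),
        "landmarks_path": manifest.landmarks_path,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_manifest(path: str | Path) -> CaseManifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    payload = yaml.safe_load(path.read_text())
    if not isinstance(payload, dict):
        raise ValidationError(f"manifest {path} must be a mapping")
    try:
        return CaseManifest(**payload)
    except TypeError as exc:
        raise ValidationError(f"malformed manifest {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Tabular reports (CSV)
# ---------------------------------------------------------------------------

def write_report(records: Sequence[MetricRecord] | Sequence[DVHRecord],
                 path: str | Path) -> None:
    """One CSV row per record; numeric values rendered at 2 decimals.

    An empty list writes the (metric-record) header only.
    """
    path = Path(path)
    if records and isinstance(records[0], DVHRecord):
        header = ["roi", "plan", "metric", "value"]
        rows = [[r.roi, r.plan, r.metric, f"{r.value:.2f}"] for r in records]
    elif records and isinstance(records[0], MetricRecord):
        header = ["region", "ASD_mm", "CD_mm", "DSC", "HD95_mm"]
        rows = [[r.region, f"{r.asd_mm:.2f}", f"{r.cd_mm:.2f}",
                 f"{r.dsc:.2f}", f"{r.hd95_mm:.2f}"] for r in records]
    elif not records:
        header = ["region", "ASD_mm", "CD_mm", "DSC", "HD95_mm"]
        rows = []
    else:
        raise ValidationError(f"unsupported record type {type(records[0]).__name__}")
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)
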