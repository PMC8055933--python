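"""File-format handling: NIfTI volumes, TSV manifests, JSON results.

Volumes are written one NIfTI file per contrast plus a lesion-label file and
a tissue-mask file per subject; covariates go to a cohort-level CSV.  All
voxel coordinates are 0-indexed; the affine is carried but inputs are
assumed to share one grid (no resampling).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import SubjectRecord

__all__ = [
    "save_subject",
    "load_subject",
    "save_cohort",
    "load_cohort",
    "write_patch_manifest",
    "read_patch_manifest",
    "write_json",
]


def _nifti(data: np.ndarray, affine=None) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(data), np.eye(4) if affine is None else affine)


def save_subject(record: SubjectRecord, outdir: Path) -> Path:
    d = Path(outdir) / record.subject_id
    d.mkdir(parents=True, exist_ok=True)
    for i, vol in enumerate(record.contrasts):
        nib.save(_nifti(vol.astype(np.float32)), d / f"contrast_{i:02d}.nii")
    nib.save(_nifti(record.lesion_labels.astype(np.int32)), d / "lesion_labels.nii")
    nib.save(_nifti(record.tissue_mask.astype(np.uint8)), d / "tissue_mask.nii")
    return d


def load_subject(subjdir: Path) -> SubjectRecord:
    d = Path(subjdir)
    paths = sorted(d.glob("contrast_*.nii"))
    if not paths:
        raise FileNotFoundError(f"no contrast volumes under {d}")
    contrasts = [np.asarray(nib.load(p).dataobj, dtype=np.float32) for p in paths]
    labels = np.asarray(nib.load(d / "lesion_labels.nii").dataobj, dtype=np.int32)
    mask = np.asarray(nib.load(d / "tissue_mask.nii").dataobj).astype(bool)
    return SubjectRecord(subject_id=d.name, contrasts=contrasts, lesion_labels=labels,
                         tissue_mask=mask, disability=np.nan, biomarker=None)


def save_cohort(records: list[SubjectRecord], outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        save_subject(rec, outdir)
    pd.DataFrame([{"subject_id": r.subject_id, "disability": r.disability,
                   "biomarker": r.biomarker} for r in records]
                 ).to_csv(outdir / "covariates.csv", index=False)


def load_cohort(outdir: Path) -> list[SubjectRecord]:
    outdir = Path(outdir)
    cov = pd.read_csv(outdir / "covariates.csv").set_index("subject_id")
    records = []
    for d in sorted(p for p in outdir.iterdir() if p.is_dir()):
        rec = load_subject(d)
        row = cov.loc[rec.subject_id]
        rec.disability = float(row["disability"])
        bio = row["biomarker"]
        rec.biomarker = None if pd.isna(bio) else float(bio)
        records.append(rec)
    return records


def write_patch_manifest(patches, path: Path) -> None:
    pd.DataFrame([{"subject_id": p.subject_id, "x": p.center[0], "y": p.center[1],
                   "z": p.center[2], "label": p.label} for p in patches]
                 ).to_csv(path, sep="\t", index=False)


def read_patch_manifest(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def _default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
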