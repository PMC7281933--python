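"""Shared format readers/writers: NIfTI volumes, b-value files, TSV tables."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .inference import grid_affine
from .preprocess import DWISeries, validate_b_values


def save_nifti(
    data: np.ndarray,
    path: str | Path,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    affine: np.ndarray | None = None,
) -> Path:
    """Write an array as NIfTI-1 (float64, so round trips are bit-exact)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = grid_affine(data.shape[:3], voxel_size_mm)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_xyzt_units(xyz="mm")
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns (data, affine, voxel_size_mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = img.header.get_zooms()[:3]
    return data, img.affine, tuple(float(z) for z in zooms)


def write_bvals(b_values, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    b = validate_b_values(np.asarray(b_values, dtype=float))
    path.write_text("\n".join(f"{v:g}" for v in b) + "\n")
    return path


def read_bvals(path: str | Path) -> np.ndarray:
    values = [float(line) for line in Path(path).read_text().split()]
    return validate_b_values(np.asarray(values))


COHORT_REQUIRED_COLUMNS = ("subject_id", "group")


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _validate_cohort(table)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    _validate_cohort(table)
    return table


def _validate_cohort(table: pd.DataFrame) -> None:
    for col in COHORT_REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"cohort table missing required column {col!r}")
    if table["subject_id"].duplicated().any():
        raise ValueError("cohort table has duplicate subject_ids")
    for col in table.columns:
        if col in COHORT_REQUIRED_COLUMNS:
            continue
        if not np.issubdtype(table[col].dtype, np.number):
            raise ValueError(f"covariate column {col!r} is not numeric")


def load_dwi(
    dwi_path: str | Path, bvals_path: str | Path, mask_path: str | Path | None = None
) -> DWISeries:
    data, _aff, voxel = load_nifti(dwi_path)
    b = read_bvals(bvals_path)
    mask = None
    if mask_path is not None:
        mdata, _, _ = load_nifti(mask_path)
        mask = mdata > 0.5
    return DWISeries(signal=data, b_values=b, voxel_size_mm=voxel, brain_mask=mask)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_of(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def check_common_grid(shapes: dict[str, tuple]) -> None:
    """Raise listing offenders if subjects are not on one common grid."""
    if not shapes:
        return
    ref = next(iter(shapes.values()))
    bad = [sid for sid, s in shapes.items() if s != ref]
    if bad:
        raise ValueError(f"subjects on mismatched grids (expected {ref}): {bad}")
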