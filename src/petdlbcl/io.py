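"""NIfTI / CSV / JSON input-output."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .records import COHORT_COLUMNS
from .segmentation import SegmentationResult
from .volume import SuvVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_label_map",
    "read_label_map",
    "write_segmentation",
    "read_cohort",
    "write_cohort",
]


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    return np.diag([spacing[0], spacing[1], spacing[2], 1.0])


def write_volume(vol: SuvVolume, path: str | Path) -> None:
    """Write an SUV volume as NIfTI-1 (float64, spacing encoded in the affine)."""
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float64), _affine(vol.spacing))
    nib.save(img, str(path))


def read_volume(path: str | Path, edit_mask: np.ndarray | None = None) -> SuvVolume:
    """Read a NIfTI SUV volume; spacing is taken from the header zooms."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    if data.size and float(data.min()) < 0:
        raise ValueError(f"{path}: field 'values' contains negative SUVs")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SuvVolume(data, spacing, edit_mask=edit_mask)


def write_mask(mask: np.ndarray, spacing, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(tuple(spacing)))
    nib.save(img, str(path))


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    return np.asarray(nib.load(str(path)).dataobj) > 0


def write_label_map(labels: np.ndarray, spacing, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int32), _affine(tuple(spacing)))
    nib.save(img, str(path))


def read_label_map(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label map not found: {path}")
    return np.asarray(nib.load(str(path)).dataobj).astype(np.int32)


def write_segmentation(seg: SegmentationResult, json_path: str | Path,
                       label_path: str | Path | None = None) -> None:
    """Persist a segmentation as JSON (+ optional NIfTI label map)."""
    Path(json_path).write_text(json.dumps(seg.to_dict(), indent=2) + "\n")
    if label_path is not None:
        write_label_map(seg.label_map, seg.spacing, label_path)


#: Quantitative columns that must be present and finite for modelling.
_REQUIRED_NUMERIC = ["mtv0", "ds", "time_years"]


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV (column dictionary in :mod:`petdlbcl.records`).

    Rows with missing key quantitative fields are flagged with a warning and
    kept (downstream stratification skips them); a structurally invalid file
    raises with the offending column named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort table not found: {path}")
    df = pd.read_csv(path)
    missing_cols = [c for c in ("time_years", "event", "mtv0", "ds") if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: cohort table lacks required column(s) {missing_cols}")
    bad = df[_REQUIRED_NUMERIC].isna().any(axis=1)
    if bad.any():
        ids = df.loc[bad, "id"].tolist() if "id" in df.columns else df.index[bad].tolist()
        warnings.warn(f"cohort rows with missing key fields (kept, will be skipped): {ids}",
                      stacklevel=2)
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if extra:
        warnings.warn(f"cohort table has unrecognised column(s) {extra}", stacklevel=2)
    return df
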