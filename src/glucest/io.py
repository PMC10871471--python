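"""File formats: NIfTI image stacks with offset sidecars, CSV/XLSX tables.

Single-slice data are stored as NIfTI volumes with a degenerate third
dimension and the saturation-offset (or flip-angle) index along the fourth
axis, so standard neuroimaging tools can open them.  Offsets travel in a
sidecar CSV with header ``frame,offset_ppm``.  Voxel indexing is 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fieldmap import OffsetStack, infer_mask
from .simulate import SaturationScheme

__all__ = [
    "write_offset_stack",
    "read_offset_stack",
    "write_map",
    "read_map",
    "write_labels",
    "read_labels",
    "write_calibration",
    "read_calibration",
    "write_manifest",
    "read_manifest",
    "read_subject_table",
    "sidecar_path_for",
]


def sidecar_path_for(img_path: str | Path) -> Path:
    p = Path(img_path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + "_offsets.csv")
    return p.with_suffix(".csv")


def _to_nifti(data: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine=np.eye(4))


def write_offset_stack(
    stack: OffsetStack, img_path: str | Path, sidecar_path: str | Path | None = None
) -> tuple[Path, Path]:
    """Write frames as (nx, ny, 1, n_offsets) NIfTI plus an offsets sidecar."""
    img_path = Path(img_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else sidecar_path_for(img_path)
    data = stack.data
    if data.ndim == 3:
        vol = data[:, :, None, :]
    else:
        raise ValueError("offset stacks are written as 2-D frames")
    img_path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(_to_nifti(vol), str(img_path))
    pd.DataFrame(
        {"frame": np.arange(stack.offsets.size), "offset_ppm": stack.offsets}
    ).to_csv(sidecar_path, index=False)
    return img_path, sidecar_path


def read_offset_stack(
    img_path: str | Path,
    scheme: SaturationScheme,
    sidecar_path: str | Path | None = None,
) -> OffsetStack:
    """Read a stack, reordering frames so offsets come out ascending.

    Raises when the sidecar's offset count does not match the number of
    frames in the image file.
    """
    img_path = Path(img_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else sidecar_path_for(img_path)
    vol = np.asarray(nib.load(str(img_path)).get_fdata())
    if vol.ndim == 4:
        if vol.shape[2] != 1:
            raise ValueError("expected single-slice data (third dimension 1)")
        frames = vol[:, :, 0, :]
    elif vol.ndim == 3:
        frames = vol
    else:
        raise ValueError(f"cannot interpret {vol.ndim}-D image as an offset stack")
    sidecar = pd.read_csv(sidecar_path)
    if "offset_ppm" not in sidecar.columns:
        raise ValueError("sidecar must have an 'offset_ppm' column")
    offsets = sidecar["offset_ppm"].to_numpy(dtype=float)
    if offsets.size != frames.shape[-1]:
        raise ValueError(
            f"sidecar lists {offsets.size} offsets but the image has "
            f"{frames.shape[-1]} frames"
        )
    order = np.argsort(offsets)
    frames = frames[..., order]
    offsets = offsets[order]
    return OffsetStack(frames, offsets, scheme, mask=infer_mask(frames))


def write_map(data: np.ndarray, path: str | Path) -> Path:
    """Write a 2-D float map as single-slice NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(_to_nifti(np.asarray(data, dtype=float)[:, :, None]), str(path))
    return path


def read_map(path: str | Path) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).get_fdata())
    return data[:, :, 0] if data.ndim == 3 else data


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(
        np.asarray(labels, dtype=np.int16)[:, :, None], affine=np.eye(4)
    )
    nib.save(img, str(path))
    return path


def read_labels(path: str | Path) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).get_fdata())
    data = data[:, :, 0] if data.ndim == 3 else data
    return np.rint(data).astype(np.int16)


def write_calibration(table: pd.DataFrame, path: str | Path) -> Path:
    """Calibration CSV with header ``kappa,glucest_percent``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[["kappa", "glucest_percent"]].to_csv(path, index=False)
    return path


def read_calibration(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if not {"kappa", "glucest_percent"} <= set(table.columns):
        raise ValueError("calibration CSV must have columns kappa,glucest_percent")
    return table


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    """Subject manifest CSV: subject_id,group,age,sex,seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest[["subject_id", "group", "age", "sex", "seed"]].to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Per-subject regional table from CSV or XLSX (real-data path).

    Expects at least subject_id, group, age, region, mean_percent columns
    (a supplementary-style spreadsheet export).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        table = pd.read_excel(path)
    else:
        table = pd.read_csv(path)
    required = {"subject_id", "group", "age", "region", "mean_percent"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"subject table is missing columns {sorted(missing)}")
    return table


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
    return path
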