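"""Shared I/O helpers: NIfTI volumes, TSV tables, and run manifests."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np


def default_affine(voxel_size: float = 3.0) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    return aff


def write_nifti(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(
        np.asarray(data), affine if affine is not None else default_affine()
    )
    nib.save(img, str(path))


def read_nifti(path) -> tuple[np.ndarray, np.ndarray, nib.Nifti1Header]:
    """Load a NIfTI file; returns (data, affine, header)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # malformed file or header
        raise ValueError(f"could not read NIfTI file {path}: {exc}") from exc
    return np.asanyarray(img.dataobj), img.affine, img.header


def write_manifest(path, **entries) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, default=str)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
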