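"""NIfTI and table I/O."""
from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BrainMask, EigenvalueVolume, ScalarMap


def save_nifti(data, spacing, path) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def _load(path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def load_scalar_map(path, kind: str, subject_id=None) -> ScalarMap:
    data, spacing = _load(path)
    return ScalarMap(data, kind, spacing=spacing, subject_id=subject_id).validate()


def load_eigenvalues(lam1_path, lam2_path, lam3_path, subject_id=None
                     ) -> EigenvalueVolume:
    vols, spacings = [], []
    for p in (lam1_path, lam2_path, lam3_path):
        d, s = _load(p)
        vols.append(d)
        spacings.append(s)
    shapes = [v.shape for v in vols]
    if len(set(shapes)) != 1:
        raise ValueError(f"eigenvalue volumes disagree on grid shape: {shapes}")
    return EigenvalueVolume(*vols, spacing=spacings[0], subject_id=subject_id)


def save_mask(mask: BrainMask, path) -> None:
    save_nifti(mask.data.astype(np.uint8), mask.spacing, path)


def load_mask(path, source_kind="FA") -> BrainMask:
    data, spacing = _load(path)
    return BrainMask(data > 0.5, spacing=spacing, source_kind=source_kind)


def load_subject_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"subject table must contain columns {sorted(required)}")
    return df
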