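"""FA and MD scalar maps from diffusion-tensor eigenvalues.

Mean diffusivity is the eigenvalue average, MD = (l1 + l2 + l3) / 3.
Fractional anisotropy is

    FA = sqrt(3/2) * sqrt(sum_k (l_k - MD)^2) / sqrt(sum_k l_k^2),

which is 0 for isotropic diffusion (l1 = l2 = l3) and 1 for completely
anisotropic diffusion (l1 > 0, l2 = l3 = 0).  Noisy tensor fits can yield
negative eigenvalues; both operations sort eigenvalues descending per voxel
and clamp negatives to zero first so FA stays in [0, 1], logging the
fraction of clamped voxels.
"""
from __future__ import annotations

import logging

import numpy as np

from .core import FA, MD, EigenvalueVolume, ScalarMap

log = logging.getLogger(__name__)


def _prepare(eigs: EigenvalueVolume) -> EigenvalueVolume:
    clean, frac = eigs.sorted_clamped()
    if frac > 0:
        log.warning(
            "subject %s: clamped negative eigenvalues in %.2f%% of voxels",
            eigs.subject_id, 100 * frac,
        )
    return clean


def compute_md(eigs: EigenvalueVolume) -> ScalarMap:
    """Mean diffusivity: voxel-wise arithmetic mean of the three eigenvalues."""
    clean = _prepare(eigs)
    md = (clean.lam1 + clean.lam2 + clean.lam3) / 3.0
    return ScalarMap(np.clip(md, 0.0, None), MD,
                     spacing=eigs.spacing, subject_id=eigs.subject_id).validate()


def compute_fa(eigs: EigenvalueVolume) -> ScalarMap:
    """Fractional anisotropy; voxels with zero total diffusion get FA = 0."""
    clean = _prepare(eigs)
    lam = clean.stacked()
    md = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((lam - md) ** 2, axis=-1))
    den2 = np.sum(lam ** 2, axis=-1)
    fa = np.zeros(clean.shape)
    nz = den2 > 0
    fa[nz] = np.sqrt(1.5) * num[nz] / np.sqrt(den2[nz])
    fa = np.clip(fa, 0.0, 1.0)
    return ScalarMap(fa, FA, spacing=eigs.spacing, subject_id=eigs.subject_id).validate()


def load_scalar_map(data, kind: str, spacing=(1.0, 1.0, 1.0), subject_id=None) -> ScalarMap:
    """Wrap a precomputed FA/MD volume, validating the map invariants."""
    return ScalarMap(data, kind, spacing=spacing, subject_id=subject_id).validate()
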