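"""Seeded two-group DTI-like phantom cohorts.

Each subject is an ellipsoidal "brain" on a zero background.  A target FA
field (baseline plus a spatially correlated Gaussian-random-field
fluctuation) and an MD field are converted voxel-wise into an axially
symmetric eigenvalue triple

    lam1 = MD (1 + 2 delta),  lam2 = lam3 = MD (1 - delta),
    delta = FA / sqrt(3 - 2 FA^2),

which reproduces the target FA and MD exactly, so the map-computation stage
is exercised on realistic inputs (the group effect is planted in eigenvalue
space, not pasted into the FA map).  Cases additionally receive a regional
FA shift and an altered texture correlation length inside a sub-ellipsoid.
Gaussian noise is added to each eigenvalue inside the brain only, leaving
the background exactly dark so threshold segmentation behaves like it does
on scanner-masked maps.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict, replace
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import EigenvalueVolume
from .dti_maps import compute_fa, compute_md


@dataclass
class EffectSpec:
    """Planted case-vs-control difference, confined to a sub-ellipsoid."""

    semi_axes_frac: float = 0.5      # effect ellipsoid axes as fraction of brain axes
    center_frac: Tuple[float, float, float] = (0.0, 0.0, 0.0)  # offset, brain-axis units
    fa_shift: float = 0.08           # added to case FA inside the region
    texture_scale_ratio: float = 1.5  # case correlation-length multiplier in region


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort."""

    n_case: int = 30
    n_control: int = 30
    shape: Tuple[int, int, int] = (48, 48, 32)
    spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_semi_axes_mm: Tuple[float, float, float] = (40.0, 36.0, 26.0)
    baseline_fa: float = 0.45
    baseline_md: float = 8.0e-4       # mm^2/s
    fa_fluct_sd: float = 0.05         # amplitude of the correlated FA texture
    md_fluct_rel_sd: float = 0.05     # relative MD texture amplitude
    corr_len_mm: float = 6.0          # texture correlation length
    subject_fa_sd: float = 0.02       # between-subject baseline FA spread
    subject_len_rel_sd: float = 0.05  # between-subject correlation-length jitter
    effect: EffectSpec = field(default_factory=EffectSpec)
    noise_sd: float = 0.02            # eigenvalue noise, relative to baseline MD
    rician_noise: bool = False
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 <= self.baseline_fa + abs(self.effect.fa_shift) <= 1.0):
            raise ValueError("fa_shift must keep FA inside [0, 1]")
        if self.effect.semi_axes_frac + max(abs(c) for c in self.effect.center_frac) > 1.0:
            raise ValueError("effect region extends outside the brain")
        return self


@dataclass
class SyntheticSubject:
    subject_id: str
    group: int                      # 1 = case, 0 = control
    eigs: EigenvalueVolume
    age: float = 0.0
    sex: str = "F"

    def fa_map(self):
        return compute_fa(self.eigs)

    def md_map(self):
        return compute_md(self.eigs)


def _geometry(spec: CohortSpec):
    grids = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(spec.shape, spec.spacing)
    ]
    x, y, z = np.meshgrid(*grids, indexing="ij")
    a, b, c = spec.brain_semi_axes_mm
    brain = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    ea = spec.effect.semi_axes_frac
    cx, cy, cz = (f * ax for f, ax in zip(spec.effect.center_frac, (a, b, c)))
    region = (((x - cx) / (ea * a)) ** 2 + ((y - cy) / (ea * b)) ** 2
              + ((z - cz) / (ea * c)) ** 2) <= 1.0
    return brain, region


def _grf(rng: np.random.Generator, shape, corr_len_vox) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    w = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(w, sigma=corr_len_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def fa_to_delta(fa: np.ndarray) -> np.ndarray:
    return fa / np.sqrt(3.0 - 2.0 * fa ** 2)


def generate_subject(spec: CohortSpec, group: int,
                     subject_seed: int) -> SyntheticSubject:
    """One phantom subject; identical seeds give identical null subjects."""
    spec.validate()
    rng = np.random.default_rng(subject_seed)
    brain, region = _geometry(spec)
    if (region & ~brain).any():
        raise ValueError("effect region extends outside the brain")

    corr_vox = [spec.corr_len_mm / s for s in spec.spacing]
    jitter = 1.0 + spec.subject_len_rel_sd * rng.standard_normal()
    corr_vox = [max(0.5, c * jitter) for c in corr_vox]

    base = spec.baseline_fa + spec.subject_fa_sd * rng.standard_normal()
    f_ctrl = _grf(rng, spec.shape, corr_vox)
    fa = base + spec.fa_fluct_sd * f_ctrl
    if group == 1:
        if spec.effect.texture_scale_ratio != 1.0:
            f_case = _grf(rng, spec.shape,
                          [c * spec.effect.texture_scale_ratio for c in corr_vox])
            w = region.astype(float)
            fa = base + spec.fa_fluct_sd * (f_ctrl * (1 - w) + f_case * w)
        fa = fa + spec.effect.fa_shift * region
    np.clip(fa, 0.0, 0.95, out=fa)

    md = spec.baseline_md * (1.0 + spec.md_fluct_rel_sd * _grf(rng, spec.shape, corr_vox))
    np.clip(md, 0.1 * spec.baseline_md, None, out=md)

    delta = fa_to_delta(fa)
    lam1 = md * (1.0 + 2.0 * delta)
    lam2 = md * (1.0 - delta)
    lam3 = lam2.copy()

    lam = np.stack([lam1, lam2, lam3], axis=-1)
    if spec.noise_sd > 0:
        sd = spec.noise_sd * spec.baseline_md
        noise = rng.normal(0.0, sd, size=lam.shape)
        if spec.rician_noise:
            lam = np.sqrt((lam + noise) ** 2
                          + rng.normal(0.0, sd, size=lam.shape) ** 2)
        else:
            lam = lam + noise
        lam *= brain[..., None]
    else:
        lam *= brain[..., None]
    lam = np.clip(np.sort(lam, axis=-1)[..., ::-1], 0.0, None)

    eigs = EigenvalueVolume(lam[..., 0], lam[..., 1], lam[..., 2],
                            spacing=spec.spacing,
                            subject_id=f"{'PD' if group else 'HC'}{subject_seed}")
    age = float(rng.normal(57.7, 7.7))
    sex = "M" if rng.random() < 0.5 else "F"
    return SyntheticSubject(eigs.subject_id, group, eigs, age=age, sex=sex)


def _subject_seeds(master_seed: int, n: int) -> List[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def generate_cohort(spec: CohortSpec, cohort: str = "train"
                    ) -> Tuple[List[SyntheticSubject], pd.DataFrame]:
    """Full seeded cohort plus a labels table in the pipeline input schema."""
    spec.validate()
    n = spec.n_case + spec.n_control
    seeds = _subject_seeds(spec.seed, n)
    subjects = []
    rows = []
    for k in range(n):
        group = 1 if k < spec.n_case else 0
        sid = f"{cohort}_{'PD' if group else 'HC'}_{k:03d}"
        subj = generate_subject(spec, group, seeds[k])
        subj = SyntheticSubject(sid, group, subj.eigs, age=subj.age, sex=subj.sex)
        subj.eigs.subject_id = sid
        subjects.append(subj)
        rows.append({"subject_id": sid, "group": group, "cohort": cohort,
                     "age": round(subj.age, 1), "sex": subj.sex})
    labels = pd.DataFrame(rows)
    return subjects, labels


def save_cohort(subjects: List[SyntheticSubject], labels: pd.DataFrame,
                out_dir) -> None:
    """Write eigenvalue NIfTIs (<sid>_lam{1,2,3}.nii.gz) and subjects.csv."""
    from pathlib import Path

    from .io import save_nifti

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        for i, lam in enumerate((s.eigs.lam1, s.eigs.lam2, s.eigs.lam3), start=1):
            save_nifti(lam, s.eigs.spacing, out / f"{s.subject_id}_lam{i}.nii.gz")
    labels.to_csv(out / "subjects.csv", index=False)


# ---------------------------------------------------------------------------
# tiny hand-checkable fixtures


@dataclass(frozen=True)
class ToyFixture:
    name: str
    array: tuple                 # nested tuples; immutable
    expected: tuple              # ((description, value), ...)

    def levels(self) -> np.ndarray:
        return np.asarray(self.array)


def toy_fixture_suite() -> List[ToyFixture]:
    """Worked micro-examples with hand-computed oracle values.

    Values were computed by direct substitution into the defining formulas
    (pair/run/zone enumeration done by hand); the tests re-derive each one
    with an independent brute-force oracle.
    """
    return [
        ToyFixture("glcm_row_1122", ((1, 1, 2, 2),),
                   (("pair counts symmetric (1,1)", 2),
                    ("pair counts symmetric (1,2)", 2),
                    ("pair counts symmetric (2,2)", 2),
                    ("contrast single-axis distance 1", 1.0 / 3.0))),
        ToyFixture("glcm_offdiag_half", ((1, 2),),
                   (("contrast of p={(1,2):.5,(2,1):.5}", 1.0),)),
        ToyFixture("glcm_diag_half", ((1, 1, 2, 2),),
                   (("imc1 of p={(1,1):.5,(2,2):.5}", -1.0),)),
        ToyFixture("glrlm_row_11222", ((1, 1, 2, 2, 2),),
                   (("long-run low-gray emphasis, one direction", 3.125),)),
        ToyFixture("glrlm_const_5", ((3, 3, 3, 3, 3),),
                   (("single run of length 5: LRE", 25.0),)),
        ToyFixture("glszm_square", ((1, 1), (2, 2)),
                   (("zone variance", 0.0),
                    ("small-area low-gray emphasis", 0.15625))),
        ToyFixture("gldm_const_cube", (((1,) * 3,) * 3,) * 3,
                   (("centre voxel dependence at alpha=0", 26),)),
        ToyFixture("hist_pm1", ((-1, -1, 1, 1),),
                   (("Pearson kurtosis of an even +-1 split", 1.0),)),
        ToyFixture("hist_onebin", ((2, 2, 2),),
                   (("uniformity, single occupied bin", 1.0),)),
        ToyFixture("fa_axial_211", ((2.0, 1.0, 1.0),),
                   (("FA of eigenvalues (2,1,1)", float(np.sqrt(1.0 / 6.0))),)),
    ]


def toy_fixture_hash() -> str:
    h = hashlib.sha256()
    for fx in toy_fixture_suite():
        h.update(fx.name.encode())
        h.update(repr(fx.array).encode())
        h.update(repr(fx.expected).encode())
    return h.hexdigest()
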