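"""End-to-end study orchestration.

maps -> mask -> transform bank -> features -> univariate screen -> LASSO
-> logistic radiomic score -> ROC, with a strict train/test firewall: test
subjects never influence screening, the lambda choice, or the fitted
coefficients.  A single config seed fans out to per-stage seeds through a
stage-name hash so each stage is individually reproducible.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .brain_mask import make_brain_mask
from .core import FA, MD, EigenvalueVolume, ScalarMap
from .dti_maps import compute_fa, compute_md
from .scoring import RadiomicScoreModel, fit_score, roc_auc, score
from .selection import FeatureTable, LassoResult, lasso_select, univariate_screen
from .texture import extract_feature_vector
from .transforms import TransformDescriptor, default_manifest, parse_descriptor

log = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    subjects_csv: Optional[str] = None
    data_dir: Optional[str] = None
    out_dir: Optional[str] = None
    sigma_mm: float = 1.0
    threshold_method: str = "otsu"
    fixed_threshold: Optional[float] = None
    ng: int = 32
    glcm_distance: int = 1
    gldm_alpha: int = 0
    manifest: Optional[List[str]] = None   # canonical strings; None = default 25
    alpha: float = 0.001
    folds: int = 5
    seed: int = 17

    def descriptors(self) -> List[TransformDescriptor]:
        if self.manifest is None:
            return default_manifest()
        return [parse_descriptor(s) for s in self.manifest]

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class StudyResult:
    features: pd.DataFrame
    labels: pd.Series
    cohorts: pd.Series
    screen: pd.DataFrame
    lasso: Optional[LassoResult]
    model: RadiomicScoreModel
    train_scores: pd.Series
    test_scores: Optional[pd.Series]
    train_roc: "object"
    test_roc: Optional["object"]
    overall_roc: Optional["object"]
    config_hash: str = ""
    seed: int = 0

    @property
    def selected(self) -> List[str]:
        return self.model.feature_ids


def subject_maps(eigs: EigenvalueVolume) -> Dict[str, ScalarMap]:
    return {FA: compute_fa(eigs), MD: compute_md(eigs)}


def extract_subject(eigs: EigenvalueVolume, config: RunConfig) -> pd.Series:
    """Maps, mask (from FA, reused for MD) and feature vector for one subject."""
    maps = subject_maps(eigs)
    mask = make_brain_mask(maps[FA], sigma_mm=config.sigma_mm,
                           method=config.threshold_method,
                           fixed_value=config.fixed_threshold)
    return extract_feature_vector(maps[FA], maps[MD], mask,
                                  manifest=config.descriptors(),
                                  Ng=config.ng,
                                  glcm_distance=config.glcm_distance,
                                  gldm_alpha=config.gldm_alpha)


def extract_cohort_features(subjects, config: RunConfig) -> pd.DataFrame:
    """Feature table (rows = subjects) from per-subject eigenvalue volumes."""
    rows = {}
    for s in subjects:
        rows[s.subject_id] = extract_subject(s.eigs, config)
    return pd.DataFrame(rows).T


def run_study(train_subjects, test_subjects, config: RunConfig) -> StudyResult:
    """Run the full workflow on in-memory subjects.

    ``train_subjects`` / ``test_subjects`` are sequences with attributes
    ``subject_id``, ``group`` and ``eigs``; test may be empty or None.
    """
    test_subjects = list(test_subjects or [])
    train_ids = {s.subject_id for s in train_subjects}
    overlap = train_ids & {s.subject_id for s in test_subjects}
    if overlap:
        raise ValueError(f"train/test subject sets overlap: {sorted(overlap)}")

    X_train = extract_cohort_features(train_subjects, config)
    y_train = pd.Series({s.subject_id: int(s.group) for s in train_subjects})
    table = FeatureTable(X_train, y_train)

    screen = univariate_screen(table, alpha=config.alpha)
    survivors = screen.loc[screen.survived, "feature_id"].tolist()
    lasso = None
    selected: List[str] = []
    if survivors:
        lasso = lasso_select(table, survivors, k=config.folds,
                             seed=stage_seed(config.seed, "lasso_cv"))
        selected = lasso.selected
    model = fit_score(table, selected)

    train_scores = pd.Series(score(model, X_train), index=X_train.index)
    train_roc = roc_auc(train_scores.to_numpy(), y_train.to_numpy())

    test_scores = test_roc = overall_roc = None
    labels = y_train.copy()
    cohorts = pd.Series("train", index=y_train.index)
    features = X_train
    if test_subjects:
        X_test = extract_cohort_features(test_subjects, config)
        y_test = pd.Series({s.subject_id: int(s.group) for s in test_subjects})
        test_scores = pd.Series(score(model, X_test), index=X_test.index)
        test_roc = roc_auc(test_scores.to_numpy(), y_test.to_numpy())
        all_scores = np.concatenate([train_scores.to_numpy(),
                                     test_scores.to_numpy()])
        all_y = np.concatenate([y_train.to_numpy(), y_test.to_numpy()])
        overall_roc = roc_auc(all_scores, all_y)
        features = pd.concat([X_train, X_test])
        labels = pd.concat([y_train, y_test])
        cohorts = pd.concat([cohorts, pd.Series("test", index=y_test.index)])

    return StudyResult(
        features=features, labels=labels, cohorts=cohorts, screen=screen,
        lasso=lasso, model=model, train_scores=train_scores,
        test_scores=test_scores, train_roc=train_roc, test_roc=test_roc,
        overall_roc=overall_roc, config_hash=config.config_hash(),
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# disk-based entry point


@dataclass
class _DiskSubject:
    subject_id: str
    group: int
    eigs: EigenvalueVolume


def _load_subjects(df: pd.DataFrame, data_dir: Path) -> List[_DiskSubject]:
    from .io import load_eigenvalues

    out = []
    for _, row in df.iterrows():
        sid = str(row.subject_id)
        paths = [data_dir / f"{sid}_lam{i}.nii.gz" for i in (1, 2, 3)]
        eigs = load_eigenvalues(*paths, subject_id=sid)
        out.append(_DiskSubject(sid, int(row.group), eigs))
    return out


def _roc_frame(r) -> pd.DataFrame:
    return pd.DataFrame({"threshold": r.thresholds, "sensitivity": r.sensitivity,
                         "specificity": r.specificity})


def run_pipeline(config: RunConfig) -> StudyResult:
    """Disk-based run: read subjects.csv + NIfTI volumes, write artifacts."""
    from .io import load_subject_table

    if config.subjects_csv is None or config.data_dir is None:
        raise ValueError("disk run needs subjects_csv and data_dir")
    df = load_subject_table(config.subjects_csv)
    data_dir = Path(config.data_dir)
    if "cohort" not in df.columns:
        df = df.assign(cohort="train")
    train = _load_subjects(df[df.cohort == "train"], data_dir)
    test = _load_subjects(df[df.cohort == "test"], data_dir)

    result = run_study(train, test, config)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamp = {"config": asdict(config), "config_hash": result.config_hash,
                 "seed": config.seed}
        (out / "config.json").write_text(json.dumps(stamp, indent=2, default=str))
        result.features.to_csv(out / "features.csv")
        result.screen.to_csv(out / "screen.csv", index=False)
        if result.lasso is not None:
            ls = result.lasso
            (out / "selection.json").write_text(json.dumps({
                "lambda_grid": ls.lambda_grid.tolist(),
                "cv_deviance": ls.cv_deviance.tolist(),
                "cv_deviance_se": ls.cv_deviance_se.tolist(),
                "lambda_min": ls.lambda_min,
                "selected": ls.selected,
                "coefficients": ls.coefficients,
                "intercept": ls.intercept,
                "fold_assignment": ls.fold_assignment,
                "seed": ls.seed,
            }, indent=2))
        m = result.model
        orig_b0, orig_terms = m.original_scale_terms()
        (out / "model.json").write_text(json.dumps({
            "intercept": m.intercept, "terms": m.terms,
            "feature_means": m.feature_means, "feature_sds": m.feature_sds,
            "original_scale": {"intercept": orig_b0, "terms": orig_terms},
            "ridge_fallback": m.ridge_fallback,
            "config_hash": result.config_hash, "seed": config.seed,
        }, indent=2))
        scores = result.train_scores.rename("rad_score").to_frame()
        scores["cohort"] = "train"
        if result.test_scores is not None:
            ts = result.test_scores.rename("rad_score").to_frame()
            ts["cohort"] = "test"
            scores = pd.concat([scores, ts])
        scores.to_csv(out / "scores.csv")
        _roc_frame(result.train_roc).to_csv(out / "roc_train.csv", index=False)
        if result.test_roc is not None:
            _roc_frame(result.test_roc).to_csv(out / "roc_test.csv", index=False)
    return result
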