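"""Two-stage feature selection.

Stage 1 screens each feature with a two-sample t-test (when both class
samples pass a Shapiro normality check at 0.05) or a Mann-Whitney U test,
keeping features with two-sided p < alpha (0.001 by default, uncorrected).

Stage 2 fits an L1-penalized logistic path over a 100-point geometric
lambda grid from lambda_max (the smallest penalty at which all coefficients
vanish) down to 1e-4 * lambda_max, picks the lambda minimizing the mean
out-of-fold binomial deviance in stratified k-fold cross-validation (ties
broken toward the larger lambda, i.e. the sparser model), and returns the
features with nonzero coefficients at that lambda.  Features are
standardized to zero mean / unit variance on the training table before
penalization so the L1 penalty treats all scales fairly.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """Subjects x features design with binary labels (case=1, control=0)."""

    X: pd.DataFrame                  # index = subject ids, columns = feature ids
    labels: pd.Series                # same index, values in {0, 1}

    def __post_init__(self):
        self.labels = self.labels.loc[self.X.index]
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing values")
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate feature ids")
        counts = self.labels.value_counts()
        if set(counts.index) != {0, 1} or counts.min() < 2:
            raise ValueError("need >= 2 subjects in each of the two classes")

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=float)

    @property
    def feature_ids(self) -> List[str]:
        return list(self.X.columns)


def univariate_screen(table: FeatureTable, alpha: float = 0.001,
                      normality_alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature two-sample test; returns a record per input feature.

    Columns: feature_id, test_used, statistic, p_value, survived.
    Constant features (in both classes combined) get p = 1 and never survive.
    """
    y = table.y.astype(bool)
    records = []
    Xv = table.X.to_numpy(dtype=float)
    for k, fid in enumerate(table.X.columns):
        a = Xv[y, k]
        b = Xv[~y, k]
        if np.ptp(Xv[:, k]) == 0:
            records.append((fid, "degenerate", 0.0, 1.0, False))
            continue
        normal = True
        for sample in (a, b):
            if np.ptp(sample) == 0 or sample.size < 3:
                normal = False
                break
            if stats.shapiro(sample).pvalue < normality_alpha:
                normal = False
                break
        if normal:
            stat, p = stats.ttest_ind(a, b)
            test = "t"
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "mann_whitney"
        p = float(p) if np.isfinite(p) else 1.0
        records.append((fid, test, float(stat), p, bool(p < alpha)))
    out = pd.DataFrame(records, columns=["feature_id", "test_used", "statistic",
                                         "p_value", "survived"])
    log.info("univariate screen: %d / %d features survive p < %g",
             int(out.survived.sum()), len(out), alpha)
    return out


@dataclass
class LassoResult:
    lambda_grid: np.ndarray
    cv_deviance: np.ndarray
    cv_deviance_se: np.ndarray
    lambda_min: float
    selected: List[str]
    coefficients: Dict[str, float]     # standardized scale, selected features only
    intercept: float
    fold_assignment: Dict[str, int]
    seed: int

    def lambda_1se(self) -> float:
        """Largest lambda with CV deviance within one SE of the minimum."""
        k = int(np.argmin(self.cv_deviance))
        bound = self.cv_deviance[k] + self.cv_deviance_se[k]
        ok = np.flatnonzero(self.cv_deviance <= bound)
        return float(self.lambda_grid[ok[0]])


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _l1_logistic(Xs: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # glmnet objective (1/n) * negloglik + lam * |beta|_1  ==  sklearn with
    # C = 1 / (n * lam); saga's proximal step yields exact zeros and leaves
    # the intercept unpenalized
    n = Xs.shape[0]
    clf = LogisticRegression(l1_ratio=1.0, C=1.0 / (n * lam), solver="saga",
                             tol=1e-8, max_iter=5000, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(Xs, y)
    return clf


def _path_fits(Xs: np.ndarray, y: np.ndarray, grid: np.ndarray):
    """Warm-started L1-logistic path over a descending lambda grid.

    Returns (intercepts, coefs) with coefs of shape (len(grid), n_features).
    Warm starts make the whole path barely more expensive than one fit and
    keep near-separable fits at tiny lambda from grinding.  The path runs at
    moderate precision — it only shapes the CV deviance curve; the model at
    the chosen lambda is refit at tight tolerance afterwards.
    """
    n = Xs.shape[0]
    clf = LogisticRegression(l1_ratio=1.0, C=1.0, solver="saga", tol=1e-4,
                             max_iter=100, warm_start=True, random_state=0)
    b0 = np.empty(len(grid))
    B = np.empty((len(grid), Xs.shape[1]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for j, lam in enumerate(grid):
            clf.C = 1.0 / (n * lam)
            clf.fit(Xs, y)
            b0[j] = clf.intercept_[0]
            B[j] = clf.coef_[0]
    return b0, B


def _deviance(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return -2.0 * (y * np.log(p) + (1 - y) * np.log(1 - p))


def fit_l1_path_at(table: FeatureTable, feature_ids: Sequence[str], lam: float):
    """Fit the penalized model at one lambda; returns (intercept, coef array)."""
    Xs, _, _ = _standardize(table.X[list(feature_ids)].to_numpy(dtype=float))
    clf = _l1_logistic(Xs, table.y, lam)
    return float(clf.intercept_[0]), clf.coef_[0].copy()


def lasso_lambda_max(table: FeatureTable, feature_ids: Sequence[str]) -> float:
    Xs, _, _ = _standardize(table.X[list(feature_ids)].to_numpy(dtype=float))
    y = table.y
    return float(np.abs(Xs.T @ (y - y.mean())).max() / len(y))


def lasso_select(table: FeatureTable, screened_ids: Sequence[str],
                 k: int = 5, seed: int = 0, n_lambda: int = 100,
                 lambda_min_ratio: float = 1e-4) -> LassoResult:
    """Cross-validated LASSO-logistic selection at minimum binomial deviance."""
    screened_ids = list(screened_ids)
    if not screened_ids:
        raise ValueError("no screened features supplied")
    y = table.y
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if k > min(n1, n0):
        raise ValueError(f"k={k} folds exceed the smaller class size {min(n1, n0)}")

    X = table.X[screened_ids].to_numpy(dtype=float)
    Xs, _, _ = _standardize(X)
    lam_max = float(np.abs(Xs.T @ (y - y.mean())).max() / len(y))
    grid = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    dev = np.full((k, n_lambda), np.nan)
    fold_of = {}
    for fold, (tr, va) in enumerate(skf.split(Xs, y)):
        for sid in table.X.index[va]:
            fold_of[sid] = fold
        b0, B = _path_fits(Xs[tr], y[tr], grid)
        eta = b0[:, None] + B @ Xs[va].T          # (n_lambda, n_val)
        p = 1.0 / (1.0 + np.exp(-eta))
        dev[fold] = _deviance(p, y[va][None, :]).mean(axis=1)
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(k)

    j_min = int(np.argmin(mean_dev))          # first minimum = largest lambda
    lam_min = float(grid[j_min])

    intercept, coef = fit_l1_path_at(table, screened_ids, lam_min)
    nz = np.flatnonzero(coef != 0.0)
    selected = [screened_ids[i] for i in nz]
    log.info("lasso: lambda_min=%.5g selects %d of %d features",
             lam_min, len(selected), len(screened_ids))
    return LassoResult(
        lambda_grid=grid, cv_deviance=mean_dev, cv_deviance_se=se_dev,
        lambda_min=lam_min, selected=selected,
        coefficients={screened_ids[i]: float(coef[i]) for i in nz},
        intercept=intercept, fold_assignment=fold_of, seed=seed,
    )


def select_features(table: FeatureTable, alpha: float = 0.001, k: int = 5,
                    seed: int = 0) -> tuple[pd.DataFrame, Optional[LassoResult]]:
    """Convenience wrapper: screen, then LASSO on the survivors.

    Returns (screen report, LassoResult or None if nothing survived).
    """
    screen = univariate_screen(table, alpha=alpha)
    survivors = screen.loc[screen.survived, "feature_id"].tolist()
    if not survivors:
        return screen, None
    return screen, lasso_select(table, survivors, k=k, seed=seed)
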