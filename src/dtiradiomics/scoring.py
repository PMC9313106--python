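"""Radiomic score model and ROC evaluation.

The radiomic score (Rad_score) is the linear predictor of a multivariable
binary logistic regression on the selected features:

    Rad_score = intercept + sum_k coefficient_k * feature_k

(features standardized with the training-table mean/SD).  The score is the
log-odds, not the sigmoid probability; ROC/AUC are identical either way.
AUC is computed as the proportion of concordant case-control pairs with
ties counted 1/2 (the Mann-Whitney statistic), and the operating point is
chosen by Youden's J = sensitivity + specificity - 1, ties broken toward
higher specificity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve

from .core import ROCResult
from .selection import FeatureTable

log = logging.getLogger(__name__)


@dataclass
class RadiomicScoreModel:
    intercept: float
    terms: List[Tuple[str, float]]            # (feature_id, coefficient), ordered
    feature_means: Dict[str, float]
    feature_sds: Dict[str, float]
    standard_errors: Dict[str, float] = field(default_factory=dict)
    training_scores: Dict[str, float] = field(default_factory=dict)
    ridge_fallback: bool = False

    @property
    def feature_ids(self) -> List[str]:
        return [fid for fid, _ in self.terms]

    def original_scale_terms(self) -> Tuple[float, List[Tuple[str, float]]]:
        """(intercept, terms) re-expressed on the unstandardized feature scale."""
        b0 = self.intercept
        out = []
        for fid, b in self.terms:
            mu, sd = self.feature_means[fid], self.feature_sds[fid]
            out.append((fid, b / sd))
            b0 -= b * mu / sd
        return b0, out


def fit_score(table: FeatureTable, selected_ids: Sequence[str]) -> RadiomicScoreModel:
    """Maximum-likelihood logistic fit of the radiomic score.

    Perfect separation (or non-convergence) triggers a ridge-stabilized
    fallback fit with a logged warning.
    """
    selected_ids = list(selected_ids)
    missing = [f for f in selected_ids if f not in table.X.columns]
    if missing:
        raise KeyError(f"selected features absent from table: {missing}")
    X = table.X[selected_ids].to_numpy(dtype=float)
    y = table.y
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd

    params = None
    ses = None
    ridge = False
    if selected_ids:
        design = sm.add_constant(Xs, has_constant="add")
        try:
            import warnings

            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and \
                    np.all(np.isfinite(res.params)) and np.all(np.abs(res.params) < 1e3):
                params = res.params
                ses = res.bse
        except Exception:
            params = None
        if params is None:
            log.warning("logistic fit unstable (separation?); using ridge fallback")
            ridge = True
            clf = LogisticRegression(C=100.0, solver="lbfgs", max_iter=10000)
            clf.fit(Xs, y)
            params = np.concatenate([clf.intercept_, clf.coef_[0]])
            ses = np.full(len(params), np.nan)
    else:
        # intercept-only model: log-odds of the case prevalence
        p1 = y.mean()
        params = np.array([np.log(p1 / (1 - p1))])
        ses = np.array([np.nan])

    intercept = float(params[0])
    terms = [(fid, float(b)) for fid, b in zip(selected_ids, params[1:])]
    model = RadiomicScoreModel(
        intercept=intercept, terms=terms,
        feature_means={f: float(m) for f, m in zip(selected_ids, mu)},
        feature_sds={f: float(s) for f, s in zip(selected_ids, sd)},
        standard_errors={f: float(s) for f, s in zip(selected_ids, ses[1:])},
        ridge_fallback=ridge,
    )
    train_scores = score(model, table.X)
    model.training_scores = {sid: float(v)
                             for sid, v in zip(table.X.index, train_scores)}
    return model


def score(model: RadiomicScoreModel, features) -> np.ndarray:
    """Rad_score of one subject (Series) or many (DataFrame rows)."""
    single = isinstance(features, pd.Series)
    df = features.to_frame().T if single else features
    out = np.full(len(df), model.intercept, dtype=float)
    for fid, b in model.terms:
        if fid not in df.columns:
            raise KeyError(f"feature {fid!r} missing from input")
        xs = (df[fid].to_numpy(dtype=float) - model.feature_means[fid]) \
            / model.feature_sds[fid]
        out += b * xs
    return float(out[0]) if single else out


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve, Mann-Whitney AUC, and the Youden-optimal cutpoint."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    fpr, tpr, thr = _sk_roc_curve(y, s)
    sens = tpr
    spec = 1.0 - fpr
    j = sens + spec - 1.0
    best = int(np.argmax(j))          # roc_curve walks from high thresholds:
    # among J-ties the first index has the lowest FPR, i.e. highest specificity
    cut = (float(thr[best]), float(spec[best]), float(sens[best]))
    return ROCResult(auc=float(auc), thresholds=thr, sensitivity=sens,
                     specificity=spec, youden_cutpoint=cut)


def group_compare(table: pd.DataFrame, group_col: str = "group",
                  continuous: Sequence[str] = ("age",),
                  categorical: Sequence[str] = ("sex",)) -> pd.DataFrame:
    """Demographic comparison between the two groups.

    Continuous variables use a Welch two-sample t-test; 2x2 categorical
    variables use Fisher's exact test (two-sided).
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError("group_compare needs exactly two groups")
    a = table[table[group_col] == groups[0]]
    b = table[table[group_col] == groups[1]]
    rows = []
    for var in continuous:
        if var not in table.columns:
            continue
        stat, p = stats.ttest_ind(a[var], b[var], equal_var=False)
        rows.append((var, "welch_t", float(stat), float(p)))
    for var in categorical:
        if var not in table.columns:
            continue
        cats = sorted(table[var].unique())
        if len(cats) != 2:
            raise ValueError(f"{var}: Fisher test needs a 2x2 table")
        tab = [[int((a[var] == c).sum()) for c in cats],
               [int((b[var] == c).sum()) for c in cats]]
        if any(sum(r) == 0 for r in tab) or any(sum(c) == 0 for c in zip(*tab)):
            raise ValueError(f"{var}: contingency table has an empty margin")
        stat, p = stats.fisher_exact(tab, alternative="two-sided")
        rows.append((var, "fisher_exact", float(stat), float(p)))
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "p_value"])


def fisher_exact_2x2(table_2x2) -> float:
    """Two-sided Fisher exact p for an explicit 2x2 count table."""
    _, p = stats.fisher_exact(np.asarray(table_2x2), alternative="two-sided")
    return float(p)
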