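"""Radiomic score fitting, scoring, ROC/AUC, demographic comparisons."""
import numpy as np
import pandas as pd
import pytest

from dtiradiomics.scoring import (fisher_exact_2x2, fit_score, group_compare,
                                  roc_auc, score)
from dtiradiomics.selection import FeatureTable

from oracles import auc_pairs


def logistic_table(rng, n=400, coefs=(1.0, -2.0, 0.5), intercept=0.0):
    X = rng.standard_normal((n, len(coefs)))
    eta = intercept + X @ np.array(coefs)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    Xdf = pd.DataFrame(X, columns=[f"f{i}" for i in range(len(coefs))])
    return FeatureTable(Xdf, pd.Series(y, index=Xdf.index))


class TestFitScore:
    def test_coefficient_sign_follows_effect(self, rng):
        X = rng.standard_normal((80, 1)) * 0.1
        y = np.r_[np.ones(40), np.zeros(40)]
        X[:40, 0] += 1.0
        t = FeatureTable(pd.DataFrame(X, columns=["f0"]),
                         pd.Series(y))
        m = fit_score(t, ["f0"])
        assert m.terms[0][1] > 0

    def test_refit_bit_identical(self, rng):
        t = logistic_table(rng)
        a = fit_score(t, t.feature_ids)
        b = fit_score(t, t.feature_ids)
        assert a.intercept == b.intercept and a.terms == b.terms

    def test_training_scores_reproduced(self, rng):
        t = logistic_table(rng)
        m = fit_score(t, t.feature_ids)
        again = score(m, t.X)
        stored = np.array([m.training_scores[s] for s in t.X.index])
        assert np.allclose(again, stored, atol=0)

    def test_separation_falls_back_to_ridge(self):
        X = pd.DataFrame({"f0": np.r_[np.ones(10), -np.ones(10)]})
        y = pd.Series(np.r_[np.ones(10), np.zeros(10)], index=X.index)
        m = fit_score(FeatureTable(X, y), ["f0"])
        assert m.ridge_fallback
        assert np.isfinite(m.terms[0][1])

    def test_parameter_recovery_within_3se(self, rng):
        t = logistic_table(rng, n=2000)
        m = fit_score(t, t.feature_ids)
        for (fid, b), true in zip(m.terms, (1.0, -2.0, 0.5)):
            # coefficients are on the standardized scale: true * sd(x) ~ true
            sd = t.X[fid].std(ddof=0)
            assert abs(b - true * sd) <= 3 * m.standard_errors[fid]


class TestScore:
    def test_mean_features_give_intercept(self, rng):
        t = logistic_table(rng)
        m = fit_score(t, t.feature_ids)
        fv = pd.Series({fid: m.feature_means[fid] for fid in m.feature_ids})
        assert score(m, fv) == pytest.approx(m.intercept)

    def test_monotone_in_positive_coefficient(self, rng):
        t = logistic_table(rng)
        m = fit_score(t, t.feature_ids)
        fid, b = next((f, c) for f, c in m.terms if c > 0)
        fv = pd.Series({f: 0.0 for f in m.feature_ids})
        lo = score(m, fv)
        fv[fid] = 1.0
        assert score(m, fv) > lo

    def test_missing_feature_named_in_error(self, rng):
        t = logistic_table(rng)
        m = fit_score(t, t.feature_ids)
        with pytest.raises(KeyError, match="f0"):
            score(m, pd.Series({"f1": 0.0, "f2": 0.0}))

    def test_original_scale_terms_equivalent(self, rng):
        t = logistic_table(rng)
        m = fit_score(t, t.feature_ids)
        b0, terms = m.original_scale_terms()
        raw = b0 + sum(t.X[f] * c for f, c in terms)
        assert np.allclose(raw.to_numpy(), score(m, t.X))


class TestROC:
    def test_perfect_ranking(self):
        r = roc_auc([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_pair_count_three_quarters(self):
        r = roc_auc([0.2, 0.4, 0.6, 0.8], [0, 1, 0, 1])
        assert r.auc == pytest.approx(0.75)

    def test_matches_exhaustive_pair_count(self, rng):
        s = rng.standard_normal(60)
        y = rng.integers(0, 2, size=60)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert roc_auc(s, y).auc == pytest.approx(auc_pairs(s, y), abs=1e-12)

    def test_curve_integration_equals_pair_count(self, rng):
        s = rng.standard_normal(200)
        y = (rng.random(200) < 0.4).astype(int)
        r = roc_auc(s, y)
        # trapezoid over the (fpr, tpr) curve: independent second computation
        fpr = 1.0 - r.specificity
        trapezoid = float(np.trapezoid(r.sensitivity, fpr))
        assert trapezoid == pytest.approx(r.auc, abs=1e-12)

    def test_complement_under_score_negation(self, rng):
        s = rng.standard_normal(50)
        y = np.r_[np.ones(25), np.zeros(25)].astype(int)
        assert roc_auc(s, y).auc + roc_auc(-s, y).auc == pytest.approx(1.0)

    def test_null_scores_near_half(self, rng):
        s = rng.standard_normal(2000)
        y = np.r_[np.ones(1000), np.zeros(1000)].astype(int)
        assert 0.45 < roc_auc(s, y).auc < 0.55

    def test_youden_cutpoint_maximizes_j(self):
        r = roc_auc([0.1, 0.2, 0.6, 0.7, 0.8], [0, 0, 1, 0, 1])
        j = r.sensitivity + r.specificity - 1
        score_at_cut = r.youden_cutpoint[1] + r.youden_cutpoint[2] - 1
        assert score_at_cut == pytest.approx(j.max())

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_fitted_training_auc_at_least_half(self, rng):
        t = logistic_table(rng, n=100)
        m = fit_score(t, t.feature_ids)
        assert roc_auc(score(m, t.X), t.y).auc >= 0.5


class TestGroupCompare:
    def test_gender_fisher_matches_printed_bound(self):
        # 15/15 vs 14/16 male/female
        rows = []
        for g, (m, f) in ((1, (15, 15)), (0, (14, 16))):
            rows += [{"group": g, "sex": "M"}] * m + [{"group": g, "sex": "F"}] * f
        rep = group_compare(pd.DataFrame(rows), continuous=())
        p = rep.loc[rep.variable == "sex", "p_value"].iloc[0]
        assert p >= 0.9999
        assert p == pytest.approx(1.0)

    def test_identical_groups_p_one(self):
        df = pd.DataFrame({"group": [0] * 5 + [1] * 5,
                           "age": [50, 55, 60, 65, 70] * 2})
        rep = group_compare(df, categorical=())
        row = rep.iloc[0]
        assert row.statistic == pytest.approx(0.0)
        assert row.p_value == pytest.approx(1.0)

    def test_diagonal_table_tiny_p(self):
        # hypergeometric tail: p = 2 / C(40, 20) ~ 1.45e-11
        assert fisher_exact_2x2([[20, 0], [0, 20]]) < 1e-9

    def test_empty_margin_rejected(self):
        df = pd.DataFrame({"group": [0, 0, 1, 1], "sex": ["M", "M", "M", "M"]})
        with pytest.raises(ValueError):
            group_compare(df, continuous=())
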