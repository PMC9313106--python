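"""Univariate screening and cross-validated LASSO-logistic selection."""
import numpy as np
import pandas as pd
import pytest

from dtiradiomics.selection import (FeatureTable, fit_l1_path_at,
                                    lasso_lambda_max, lasso_select,
                                    select_features, univariate_screen)


def make_table(X, n_case):
    X = pd.DataFrame(np.asarray(X, dtype=float),
                     columns=[f"f{i}" for i in range(np.asarray(X).shape[1])])
    y = pd.Series(np.r_[np.ones(n_case), np.zeros(len(X) - n_case)],
                  index=X.index)
    return FeatureTable(X, y)


class TestScreen:
    def test_strong_effect_survives(self, rng):
        X = rng.standard_normal((60, 3))
        X[:30, 0] += 10.0
        screen = univariate_screen(make_table(X, 30))
        assert bool(screen.loc[screen.feature_id == "f0", "survived"].iloc[0])

    def test_alpha_zero_kills_everything(self, rng):
        X = rng.standard_normal((40, 5))
        X[:20] += 5.0
        screen = univariate_screen(make_table(X, 20), alpha=0.0)
        assert not screen.survived.any()

    def test_constant_feature_never_survives(self, rng):
        X = rng.standard_normal((20, 2))
        X[:, 1] = 3.0
        screen = univariate_screen(make_table(X, 10))
        row = screen[screen.feature_id == "f1"].iloc[0]
        assert row.p_value == 1.0 and not row.survived

    def test_test_choice_rule(self, rng):
        # clearly non-normal sample in one class forces Mann-Whitney
        X = rng.standard_normal((60, 2))
        X[:30, 1] = np.exp(4 * rng.standard_normal(30)) ** 2
        screen = univariate_screen(make_table(X, 30))
        assert screen.loc[screen.feature_id == "f1", "test_used"].iloc[0] == \
            "mann_whitney"
        assert set(screen.test_used) <= {"t", "mann_whitney", "degenerate"}

    def test_null_survivor_rate_near_alpha(self, rng):
        X = rng.standard_normal((60, 500))
        screen = univariate_screen(make_table(X, 30), alpha=0.01)
        # binomial(500, 0.01): 99.9% envelope
        assert screen.survived.sum() <= 17


class TestLasso:
    def test_zero_selected_at_lambda_max(self, rng):
        t = make_table(rng.standard_normal((40, 30)), 20)
        lam_max = lasso_lambda_max(t, t.feature_ids)
        _, coef = fit_l1_path_at(t, t.feature_ids, lam_max)
        assert np.all(coef == 0.0)

    def test_planted_features_recovered(self, rng):
        X = rng.standard_normal((60, 50))
        X[:30, :3] += 2.5
        t = make_table(X, 30)
        res = lasso_select(t, t.feature_ids, k=5, seed=4)
        assert {"f0", "f1", "f2"}.issubset(set(res.selected))

    def test_duplicate_column_not_selected_with_opposite_signs(self, rng):
        X = rng.standard_normal((60, 10))
        X[:30, 0] += 2.0
        X[:, 1] = X[:, 0]
        t = make_table(X, 30)
        res = lasso_select(t, t.feature_ids, k=5, seed=0)
        c0 = res.coefficients.get("f0", 0.0)
        c1 = res.coefficients.get("f1", 0.0)
        assert not (c0 * c1 < 0)

    def test_seed_reproducibility(self, rng):
        X = rng.standard_normal((40, 20))
        X[:20, :2] += 1.5
        t = make_table(X, 20)
        a = lasso_select(t, t.feature_ids, k=4, seed=11)
        b = lasso_select(t, t.feature_ids, k=4, seed=11)
        assert a.selected == b.selected
        assert a.lambda_min == b.lambda_min
        assert a.coefficients == b.coefficients
        assert a.fold_assignment == b.fold_assignment

    def test_k_exceeding_class_size_rejected(self, rng):
        t = make_table(rng.standard_normal((8, 4)), 4)
        with pytest.raises(ValueError, match="folds"):
            lasso_select(t, t.feature_ids, k=5, seed=0)

    def test_ties_break_toward_larger_lambda(self, rng):
        X = rng.standard_normal((40, 10))
        X[:20, 0] += 3.0
        t = make_table(X, 20)
        res = lasso_select(t, t.feature_ids, k=4, seed=2)
        j = np.flatnonzero(res.cv_deviance == res.cv_deviance.min())
        assert res.lambda_min == res.lambda_grid[j[0]]
        assert res.lambda_grid[j[0]] == res.lambda_grid[j].max()

    def test_one_se_lambda_not_smaller_than_min(self, rng):
        X = rng.standard_normal((40, 15))
        X[:20, 0] += 2.0
        t = make_table(X, 20)
        res = lasso_select(t, t.feature_ids, k=4, seed=3)
        assert res.lambda_1se() >= res.lambda_min


class TestTwoStage:
    def test_selection_subset_of_survivors(self, rng):
        X = rng.standard_normal((60, 80))
        X[:30, :4] += 2.0
        t = make_table(X, 30)
        screen, lasso = select_features(t, alpha=0.001, k=5, seed=9)
        survivors = set(screen.loc[screen.survived, "feature_id"])
        assert lasso is not None
        assert set(lasso.selected) <= survivors

    def test_no_survivors_short_circuit(self, rng):
        X = rng.standard_normal((20, 10))
        t = make_table(X, 10)
        screen, lasso = select_features(t, alpha=1e-12, k=5, seed=0)
        assert lasso is None


class TestTable:
    def test_missing_values_rejected(self):
        X = pd.DataFrame({"a": [1.0, np.nan, 2.0, 3.0]})
        y = pd.Series([1, 1, 0, 0], index=X.index)
        with pytest.raises(ValueError, match="missing"):
            FeatureTable(X, y)

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError):
            FeatureTable(X, pd.Series([1, 1, 1, 1], index=X.index))
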