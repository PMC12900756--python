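"""Feature-selection cascade: standardization, univariate tests, correlation
pruning, LASSO."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.linear_model import LogisticRegression

from habitomics import (
    correlation_prune,
    lasso_select,
    select_features,
    univariate_filter,
    zscore_fit_apply,
)


class TestZscore:
    def test_population_sd_convention_on_1_2_3(self):
        train = pd.DataFrame({"f": [1.0, 2.0, 3.0]})
        [z], mu, sd = zscore_fit_apply(train)
        expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
        assert np.allclose(z["f"], expected)
        assert sd["f"] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_constant_column_dropped_with_warning(self, rng):
        train = pd.DataFrame({"a": rng.normal(size=5), "b": np.ones(5)})
        with pytest.warns(UserWarning, match="constant"):
            [z], *_ = zscore_fit_apply(train)
        assert list(z.columns) == ["a"]

    def test_test_rows_use_training_parameters(self, rng):
        train = pd.DataFrame({"f": rng.normal(5, 2, 50)})
        test = pd.DataFrame({"f": [train["f"].mean()]})
        [ztr, zte], *_ = zscore_fit_apply(train, test)
        assert zte["f"].iloc[0] == pytest.approx(0.0, abs=1e-12)


class TestUnivariateFilter:
    def test_identical_distribution_dropped(self, rng):
        x = rng.normal(size=60)
        table = pd.DataFrame({"flat": np.concatenate([x[:30], x[:30]])})
        y = np.array([0] * 30 + [1] * 30)
        out = univariate_filter(table, y)
        assert not out.loc["flat", "kept"]

    def test_two_sd_shift_retained_with_tiny_p(self, rng):
        table = pd.DataFrame(
            {"s": np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)])}
        )
        y = np.array([0] * 50 + [1] * 50)
        out = univariate_filter(table, y)
        assert out.loc["s", "kept"]
        assert out.loc["s", "p"] < 1e-3

    def test_mwu_branch_close_to_exact_enumeration(self):
        # heavily non-normal toy data forces the MWU branch
        x0 = np.array([0.0, 0.0, 0.0, 1.0, 50.0])
        x1 = np.array([3.0, 4.0, 60.0, 70.0, 80.0])
        table = pd.DataFrame({"f": np.concatenate([x0, x1])})
        y = np.array([0] * 5 + [1] * 5)
        out = univariate_filter(table, y)
        assert out.loc["f", "test"] == "MWU"
        exact = stats.mannwhitneyu(x0, x1, alternative="two-sided", method="exact")
        assert out.loc["f", "p"] == pytest.approx(exact.pvalue, abs=0.03)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            univariate_filter(pd.DataFrame({"f": rng.normal(size=4)}), np.ones(4))


class TestCorrelationPrune:
    def test_duplicate_column_keeps_smaller_p(self, rng):
        x = rng.normal(size=40)
        table = pd.DataFrame({"dup1": x, "dup2": x.copy()})
        p = pd.Series({"dup1": 0.04, "dup2": 0.01})
        kept, dropped = correlation_prune(table, ["dup1", "dup2"], p)
        assert kept == ["dup2"]
        assert dropped[0][1] == "dup1"

    def test_uncorrelated_set_unchanged(self, rng):
        table = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("abcde"))
        p = pd.Series(0.01, index=list("abcde"))
        kept, dropped = correlation_prune(table, list("abcde"), p)
        assert sorted(kept) == list("abcde")
        assert dropped == []

    def test_final_set_pairwise_below_threshold(self, rng):
        base = rng.normal(size=(100, 3))
        mix = base @ rng.normal(size=(3, 12)) + 0.1 * rng.normal(size=(100, 12))
        cols = [f"f{i}" for i in range(12)]
        table = pd.DataFrame(mix, columns=cols)
        p = pd.Series(rng.random(12), index=cols)
        kept, _ = correlation_prune(table, cols, p, r_threshold=0.9)
        corr = table[kept].corr().abs().to_numpy()
        off = corr[~np.eye(len(kept), dtype=bool)]
        assert (off <= 0.9 + 1e-12).all()


class TestLasso:
    def test_huge_lambda_shrinks_everything_to_zero(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
        y = rng.integers(0, 2, 60)
        lam, path, selected, _ = lasso_select(
            X, y, n_folds=5, lambda_grid=np.array([50.0, 100.0]), seed=0
        )
        assert selected == {}

    def test_tiny_lambda_matches_unpenalized_fit(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        logits = 1.2 * X["a"] - 0.8 * X["b"]
        y = (rng.random(200) < 1 / (1 + np.exp(-logits))).astype(int)
        lam, _, selected, intercept = lasso_select(
            X, y, n_folds=5, lambda_grid=np.array([1e-7, 2e-7]), seed=0
        )
        ref = LogisticRegression(penalty=None, max_iter=5000).fit(X, y)
        coef = np.array([selected.get(c, 0.0) for c in X.columns])
        assert np.allclose(coef, ref.coef_.ravel(), rtol=1e-3, atol=1e-3)

    def test_planted_signal_recovery(self, rng):
        hits = 0
        runs = 4
        for seed in range(runs):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(
                r.normal(size=(200, 50)), columns=[f"f{i}" for i in range(50)]
            )
            informative = [f"f{i}" for i in range(5)]
            logits = X[informative].sum(axis=1) * 1.0
            y = (r.random(200) < 1 / (1 + np.exp(-logits))).astype(int)
            _, _, selected, _ = lasso_select(X, y, n_folds=10, seed=seed)
            found = sum(f in selected for f in informative)
            hits += found >= 4
        assert hits >= 3

    def test_same_seed_same_selection(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 10)))
        X.columns = [f"f{i}" for i in range(10)]
        y = rng.integers(0, 2, 80)
        a = lasso_select(X, y, seed=3)
        b = lasso_select(X, y, seed=3)
        assert a[0] == b[0] and a[2] == b[2]


class TestCascade:
    def test_selected_features_survive_every_stage(self, rng):
        n = 120
        X = pd.DataFrame(
            rng.normal(size=(n, 30)), columns=[f"f{i}" for i in range(30)]
        )
        X["f1"] += 0.0  # keep
        y = (rng.random(n) < 1 / (1 + np.exp(-(1.5 * X["f0"] - 1.0 * X["f2"])))).astype(int)
        result, train_z, _ = select_features(X, y, seed=0)
        uni_kept = set(result.univariate.index[result.univariate["kept"]])
        dropped = {d for _, d, _ in result.pruned_pairs}
        for f in result.selected:
            assert f in uni_kept or len(uni_kept) == 0
            assert f not in dropped
        assert list(train_z.columns) == list(result.selected)
        assert result.lasso_lambda in result.lasso_path["lambda"].to_numpy()
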