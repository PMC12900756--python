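"""ROC/AUC, DeLong inference, threshold metrics, calibration, DCA,
attributions and baseline statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from habitomics import (
    baseline_comparison,
    calibration_curve,
    decision_curve,
    delong_ci,
    delong_test,
    roc_auc,
    threshold_metrics,
    youden_threshold,
)
from habitomics.evaluation import attribution_summary


def _pair_count_auc(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 10, [0, 1] * 5) == 0.5

    def test_matches_pair_count_oracle_exactly(self, rng):
        for _ in range(50):
            n = 20
            scores = rng.integers(0, 8, n).astype(float)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                _pair_count_auc(scores, labels), abs=1e-12
            )

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestDelongCi:
    def test_point_estimate_matches_roc_auc(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        auc, lo, hi = delong_ci(scores, labels)
        assert auc == roc_auc(scores, labels)
        assert lo <= auc <= hi

    def test_width_shrinks_with_sample_size(self, rng):
        widths = []
        for n in (50, 200, 800):
            s = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)])
            y = np.array([0] * n + [1] * n)
            _, lo, hi = delong_ci(s, y)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]
        # ~1/sqrt(n) rate: 16x n -> ~4x narrower, allow slack
        assert widths[0] / widths[2] > 2.5

    def test_coverage_at_nominal_95(self, rng):
        # true AUC for N(0,1) vs N(1,1): Phi(1/sqrt(2))
        true_auc = stats.norm.cdf(1 / np.sqrt(2))
        hits = 0
        reps = 300
        for _ in range(reps):
            s = np.concatenate([rng.normal(0, 1, 40), rng.normal(1, 1, 25)])
            y = np.array([0] * 40 + [1] * 25)
            _, lo, hi = delong_ci(s, y)
            hits += lo <= true_auc <= hi
        assert hits / reps >= 0.90


class TestDelongTest:
    def test_model_vs_itself_gives_p_one(self, rng):
        s = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        z, p = delong_test(s, s, y)
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self, rng):
        y = rng.integers(0, 2, 80)
        a, b = rng.normal(size=80), rng.normal(size=80)
        z1, p1 = delong_test(a, b, y)
        z2, p2 = delong_test(b, a, y)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_type_i_error_within_band(self, rng):
        rejections = 0
        reps = 500
        for _ in range(reps):
            y = np.array([0] * 200 + [1] * 200)
            a = rng.normal(size=400)
            b = rng.normal(size=400)
            _, p = delong_test(a, b, y)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_matches_reference_case_from_proc(self):
        """Frozen cross-check: values computed independently with R pROC."""
        rng = np.random.default_rng(2024)
        y = rng.integers(0, 2, 40)
        a = rng.normal(size=40)
        b = a + rng.normal(0, 0.8, 40)
        z, p = delong_test(a, b, y)
        auc, lo, hi = delong_ci(a, y)
        # reference values from pROC: roc.test(method="delong") and
        # ci.auc(method="delong") with direction "<"
        assert z == pytest.approx(-1.564975271559, abs=1e-9)
        assert p == pytest.approx(0.117588707638, abs=1e-9)
        assert auc == pytest.approx(0.363636363636, abs=1e-9)
        assert lo == pytest.approx(0.184648620290, abs=1e-9)
        assert hi == pytest.approx(0.542624106983, abs=1e-9)


class TestThresholdMetrics:
    def test_2x2_closed_form(self):
        scores = np.array([1] * 9 + [0] * 2 + [1] * 5 + [0] * 30, dtype=float)
        labels = np.array([1] * 11 + [0] * 35)
        m = threshold_metrics(scores, labels, 0.5)
        assert m["sensitivity"] == pytest.approx(9 / 11)
        assert m["specificity"] == pytest.approx(30 / 35)
        assert m["ppv"] == pytest.approx(9 / 14)
        assert m["npv"] == pytest.approx(30 / 32)

    def test_perfect_scores(self):
        m = threshold_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5)
        assert all(m[k] == 1.0 for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv"))

    def test_matches_bruteforce_confusion(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        thr = youden_threshold(scores, labels)
        m = threshold_metrics(scores, labels, thr)
        pred = scores >= thr
        tp = ((pred == 1) & (labels == 1)).sum()
        tn = ((pred == 0) & (labels == 0)).sum()
        assert m["accuracy"] == pytest.approx((tp + tn) / 40)


class TestCalibration:
    def test_well_calibrated_synthetic_probabilities(self, rng):
        p = rng.random(5000)
        y = (rng.random(5000) < p).astype(int)
        bins, brier = calibration_curve(p, y)
        gaps = np.abs(
            np.array(bins["mean_predicted"]) - np.array(bins["observed_fraction"])
        )
        assert gaps.max() < 0.05

    def test_constant_half_predictor_brier(self):
        y = np.array([0, 1] * 50)
        _, brier = calibration_curve(np.full(100, 0.5), y)
        assert brier == pytest.approx(0.25)

    def test_more_bins_than_samples_warns(self, rng):
        with pytest.warns(UserWarning):
            calibration_curve(rng.random(5), rng.integers(0, 2, 5), n_bins=10)


class TestDecisionCurve:
    def test_treat_none_zero_everywhere(self, rng):
        out = decision_curve(rng.random(50), rng.integers(0, 2, 50))
        assert (out["treat_none"] == 0).all()

    def test_treat_all_closed_form_at_prevalence(self):
        y = np.array([1] * 25 + [0] * 75)
        out = decision_curve(np.full(100, 0.5), y, thresholds=np.array([0.25]))
        assert out["treat_all"].iloc[0] == pytest.approx(0.25 - 0.75 * (0.25 / 0.75))

    def test_perfect_predictor_net_benefit_equals_prevalence(self):
        y = np.array([1] * 30 + [0] * 70)
        p = y.astype(float) * 0.9 + 0.05
        out = decision_curve(p, y, thresholds=np.arange(0.1, 0.9, 0.1))
        assert np.allclose(out["net_benefit"], 0.3)

    def test_model_never_beats_perfect_predictor(self, rng):
        y = rng.integers(0, 2, 200)
        perfect = y * 0.98 + 0.01
        model = np.clip(perfect + rng.normal(0, 0.3, 200), 0, 1)
        grid = np.arange(0.05, 0.95, 0.05)
        nb_perfect = decision_curve(perfect, y, grid)["net_benefit"]
        nb_model = decision_curve(model, y, grid)["net_benefit"]
        assert (nb_model <= nb_perfect + 1e-12).all()


class TestAttribution:
    def test_constant_model_zero_attributions(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 3)), columns=list("abc"))
        attr, ranking, base = attribution_summary(
            lambda A: np.full(len(A), 0.4), X, X, n_permutations=4
        )
        assert np.allclose(attr.to_numpy(), 0.0)
        assert base == pytest.approx(0.4)

    def test_local_accuracy_exact(self, rng):
        from scipy.special import expit

        X = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"))
        w = np.array([1.0, -2.0, 0.5, 0.0])
        f = lambda A: expit(np.asarray(A) @ w)
        attr, _, base = attribution_summary(f, X, X, n_permutations=6, seed=1)
        totals = attr.sum(axis=1) + base
        assert np.allclose(totals, f(X.to_numpy()), atol=1e-10)

    def test_additive_model_sign_matches_coefficient(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["u", "v"])
        f = lambda A: 0.3 * np.asarray(A)[:, 0] - 0.2 * np.asarray(A)[:, 1]
        attr, ranking, base = attribution_summary(f, X, X, n_permutations=8, seed=0)
        centered = X - X.mean(axis=0)
        assert (np.sign(attr["u"]) == np.sign(centered["u"])).mean() > 0.9
        assert (np.sign(attr["v"]) == np.sign(-centered["v"])).mean() > 0.9

    def test_empty_background_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 2)))
        with pytest.raises(ValueError):
            attribution_summary(lambda A: np.zeros(len(A)), X, X.iloc[:0])


class TestBaselineComparison:
    def test_fisher_matches_hypergeometric_enumeration(self):
        # 2x2 table {1,9; 8,2}
        x = pd.DataFrame({"v": [0] * 10 + [1] * 10})
        y = np.array([0] * 1 + [1] * 9 + [0] * 8 + [1] * 2)
        out = baseline_comparison(x, y)
        assert out.loc["v", "test"] == "fisher"
        _, p_ref = stats.fisher_exact([[1, 9], [8, 2]])
        assert out.loc["v", "p"] == pytest.approx(p_ref, rel=1e-12)

    def test_chi2_used_when_expected_counts_large(self, rng):
        x = pd.DataFrame({"v": rng.integers(0, 2, 400)})
        y = rng.integers(0, 2, 400)
        out = baseline_comparison(x, y)
        assert out.loc["v", "test"] == "chi2"

    def test_identical_continuous_groups_give_p_one(self):
        x = pd.DataFrame({"v": np.tile(np.arange(10, dtype=float), 2) + 0.123})
        y = np.array([0] * 10 + [1] * 10)
        out = baseline_comparison(x, y, categorical_max_levels=3)
        assert out.loc["v", "p"] > 0.99

    def test_continuous_shift_detected(self, rng):
        x = pd.DataFrame({"v": np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)])})
        y = np.array([0] * 50 + [1] * 50)
        out = baseline_comparison(x, y)
        assert out.loc["v", "p"] < 1e-4
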