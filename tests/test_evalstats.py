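"""Classification metrics against hand arithmetic and a Mann-Whitney oracle;
MLE distribution fits against closed forms and scipy cross-checks."""

import math

import numpy as np
import pytest
from scipy import stats

from lncdisc import evalstats


def mann_whitney_auc(y_true, y_score):
    """O(n^2) probability that a random positive outscores a random negative."""
    pos = y_score[y_true == 1]
    neg = y_score[y_true == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class TestClassificationMetrics:
    def test_perfect_separation_all_ones(self):
        y = np.array([1, 1, 0, 0])
        p = np.array([0.9, 0.9, 0.1, 0.1])
        m = evalstats.classification_metrics(y, p)
        for v in (m.accuracy, m.precision, m.recall, m.roc_auc, m.prc_auc, m.f1):
            assert v == pytest.approx(1.0)

    def test_hand_confusion_table(self):
        # TP=40, FP=10, FN=20, TN=30
        y = np.array([1] * 40 + [0] * 10 + [1] * 20 + [0] * 30)
        p = np.array([0.9] * 40 + [0.9] * 10 + [0.1] * 20 + [0.1] * 30)
        m = evalstats.classification_metrics(y, p)
        assert m.confusion == ((30, 10), (20, 40))
        assert m.accuracy == pytest.approx(0.7)
        assert m.precision == pytest.approx(0.8)
        assert m.recall == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(0.727273, abs=1e-6)

    def test_roc_auc_matches_mann_whitney_oracle(self, rng):
        y = rng.integers(0, 2, size=200)
        y[:2] = [0, 1]  # both classes present
        scores = np.round(rng.random(200), 2)  # force ties
        ours = evalstats.roc_auc(y, scores)
        assert ours == pytest.approx(mann_whitney_auc(y, scores), abs=1e-10)

    def test_roc_auc_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        y = rng.integers(0, 2, size=150)
        y[:2] = [0, 1]
        scores = rng.random(150)
        assert evalstats.roc_auc(y, scores) == pytest.approx(
            sk.roc_auc_score(y, scores), abs=1e-12
        )

    def test_average_precision_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        y = rng.integers(0, 2, size=150)
        y[:2] = [0, 1]
        scores = rng.random(150)
        assert evalstats.average_precision(y, scores) == pytest.approx(
            sk.average_precision_score(y, scores), abs=1e-12
        )

    def test_permuted_pairing_gives_null_auc(self, rng):
        n = 2000
        y = np.array([0, 1] * (n // 2))
        scores = rng.random(n)
        auc = evalstats.roc_auc(y, scores)
        assert abs(auc - 0.5) < 3 / math.sqrt(n)

    def test_no_positive_predictions_precision_zero_flagged(self):
        y = np.array([1, 0, 1, 0])
        p = np.array([0.1, 0.1, 0.2, 0.3])
        m = evalstats.classification_metrics(y, p)
        assert m.precision == 0.0 and not m.precision_defined


class TestFitDistribution:
    def test_exponential_closed_form(self):
        x = np.full(10, 4.0)
        fit = evalstats.fit_distribution(x, "exponential")
        assert fit.params["rate"] == pytest.approx(0.25, rel=1e-14)
        assert fit.loglik == pytest.approx(10 * (math.log(0.25) - 1), rel=1e-12)
        assert fit.aic == pytest.approx(2 - 2 * fit.loglik)

    def test_lognormal_closed_form_on_constant_sample_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            evalstats.fit_distribution(np.full(5, 2.0), "lognormal")

    def test_lognormal_recovery(self):
        rng = np.random.default_rng(42)
        x = rng.lognormal(mean=1.0, sigma=0.5, size=5000)
        fit = evalstats.fit_distribution(x, "lognormal")
        assert fit.params["mu"] == pytest.approx(1.0, abs=0.03)
        assert fit.params["sigma"] == pytest.approx(0.5, abs=0.02)

    def test_lognormal_matches_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(0.5, 0.8, size=400)
        fit = evalstats.fit_distribution(x, "lognormal")
        shape, loc, scale = stats.lognorm.fit(x, floc=0)
        assert fit.params["sigma"] == pytest.approx(shape, rel=1e-6)
        assert fit.params["mu"] == pytest.approx(math.log(scale), rel=1e-6)
        assert fit.loglik == pytest.approx(
            stats.lognorm.logpdf(x, shape, loc, scale).sum(), rel=1e-10
        )

    def test_gamma_matches_scipy(self):
        rng = np.random.default_rng(4)
        x = rng.gamma(shape=2.5, scale=1.7, size=1000)
        fit = evalstats.fit_distribution(x, "gamma")
        a, loc, scale = stats.gamma.fit(x, floc=0)
        assert fit.params["shape"] == pytest.approx(a, rel=1e-5)
        assert 1 / fit.params["rate"] == pytest.approx(scale, rel=1e-5)
        assert fit.loglik == pytest.approx(
            stats.gamma.logpdf(x, a, loc, scale).sum(), rel=1e-8
        )

    def test_nonpositive_samples_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            evalstats.fit_distribution(np.array([1.0, 0.0, 2.0]), "exponential")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown family"):
            evalstats.fit_distribution(np.array([1.0, 2.0]), "weibull")


class TestSelectBestFit:
    def test_lognormal_data_selects_lognormal_across_seeds(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x = rng.lognormal(1.0, 0.5, size=2000)
            best, _ = evalstats.select_best_fit(x)
            hits += best == "lognormal"
        assert hits >= 29

    def test_exponential_data_prefers_exponential(self):
        # gamma nests the exponential (shape 1), so AIC concedes to gamma
        # whenever the likelihood gain exceeds the penalty — a ~16% event
        # under the null (P(chi2_1 > 2)); exponential must still be the
        # clear modal choice and lognormal should essentially never win.
        hits = {"exponential": 0, "gamma": 0, "lognormal": 0}
        for seed in range(30):
            rng = np.random.default_rng(seed)
            best, _ = evalstats.select_best_fit(rng.exponential(2.0, size=2000))
            hits[best] += 1
        assert hits["exponential"] >= 18
        assert hits["exponential"] > hits["gamma"]
        assert hits["lognormal"] <= 1

    def test_selection_invariant_under_positive_rescaling(self):
        for seed, sampler in ((0, "lognormal"), (1, "exponential")):
            rng = np.random.default_rng(seed)
            x = (
                rng.lognormal(1.0, 0.5, size=3000)
                if sampler == "lognormal"
                else rng.exponential(1.5, size=3000)
            )
            best1, _ = evalstats.select_best_fit(x)
            best2, _ = evalstats.select_best_fit(x * 7.3)
            assert best1 == best2 == sampler

    def test_degenerate_two_point_sample_errors_not_crashes(self):
        with pytest.raises(ValueError):
            evalstats.select_best_fit(np.array([1.0, 1.0]))
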