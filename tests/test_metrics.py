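import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pubag.metrics import (bedroc, bedroc_random_expectation,
                           confusion_metrics, hit_rate_and_ef, rank_average)


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        truth = [1, 1, 0, 0, 1]
        rep = confusion_metrics(truth, truth)
        assert rep.sen == rep.spe == rep.acc == rep.f1 == 1.0

    def test_all_predicted_positive_extreme_imbalance(self):
        # 31 actives vs 8906 inactives, constant-positive prediction
        truth = np.r_[np.ones(31), np.zeros(8906)]
        rep = confusion_metrics(truth, np.ones_like(truth))
        assert rep.sen == 1.0 and rep.spe == 0.0
        assert rep.tp == 31 and rep.fp == 8906

    def test_no_positives_gives_nan_with_warning(self):
        with pytest.warns(RuntimeWarning, match="sensitivity"):
            rep = confusion_metrics([0, 0, 0], [0, 1, 0])
        assert math.isnan(rep.sen)
        assert not math.isnan(rep.spe)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_metrics([1, 0], [1])


def brute_force_bedroc(scores, truth, alpha):
    """Independent enumeration: sort, loop over active ranks, apply the
    exponential-sum definition term by term with plain floats."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    n = len(scores)
    ranks = [r + 1 for r, i in enumerate(order) if truth[i] == 1]
    n_act = len(ranks)
    ra = n_act / n
    s = 0.0
    for r in ranks:
        s += math.exp(-alpha * r / n)
    rie = (s / n_act) / ((1 / n) * (1 - math.exp(-alpha))
                         / (math.exp(alpha / n) - 1))
    return (rie * ra * math.sinh(alpha / 2)
            / (math.cosh(alpha / 2) - math.cosh(alpha / 2 - alpha * ra))
            + 1 / (1 - math.exp(alpha * (1 - ra))))


class TestBedroc:
    def test_matches_brute_force_small_n(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            n = int(rng.integers(2, 21))
            truth = np.zeros(n, dtype=int)
            truth[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            scores = rng.permutation(n).astype(float)  # distinct scores
            for alpha in (5.0, 20.0, 80.5):
                assert bedroc(scores, truth, alpha) == pytest.approx(
                    brute_force_bedroc(scores, truth, alpha), abs=1e-10)

    def test_perfect_ranking_is_one(self):
        n, na = 1000, 50
        scores = np.arange(n, 0, -1, dtype=float)
        truth = np.r_[np.ones(na, dtype=int), np.zeros(n - na, dtype=int)]
        assert bedroc(scores, truth, 80.5) == pytest.approx(1.0, abs=1e-9)

    def test_worst_ranking_is_zero(self):
        n, na = 1000, 50
        scores = np.arange(n, 0, -1, dtype=float)
        truth = np.r_[np.zeros(n - na, dtype=int), np.ones(na, dtype=int)]
        assert bedroc(scores, truth, 80.5) < 1e-6

    def test_agrees_with_rdkit(self):
        from rdkit.ML.Scoring.Scoring import CalcBEDROC
        rng = np.random.default_rng(3)
        scores = rng.random(500)
        truth = (rng.random(500) < 0.1).astype(int)
        ranked = [(s, t) for s, t in
                  sorted(zip(scores, truth), key=lambda x: -x[0])]
        assert bedroc(scores, truth, 80.5) == pytest.approx(
            CalcBEDROC(ranked, 1, 80.5), abs=1e-9)

    def test_monte_carlo_matches_random_expectation(self):
        n, na, alpha, trials = 1000, 50, 80.5, 2000
        rng = np.random.default_rng(7)
        truth = np.r_[np.ones(na, dtype=int), np.zeros(n - na, dtype=int)]
        vals = []
        for _ in range(trials):
            scores = rng.permutation(n).astype(float)
            vals.append(bedroc(scores, truth, alpha))
        se = np.std(vals) / math.sqrt(trials)
        expected = bedroc_random_expectation(n, na, alpha)
        assert abs(np.mean(vals) - expected) < 3 * se + 1e-3

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            bedroc([1.0, 0.5], [1, 1], 80.5)

    def test_ties_warn(self):
        with pytest.warns(RuntimeWarning, match="tied"):
            bedroc([0.5, 0.5, 0.1], [1, 0, 0], 80.5)


class TestHitRateAndEf:
    def test_toy_top_fraction(self):
        # 200 compounds, 10 actives, both top-1% compounds active
        scores = np.arange(200, 0, -1, dtype=float)
        truth = np.zeros(200, dtype=int)
        truth[:2] = 1
        truth[[50, 60, 70, 80, 90, 100, 110, 120]] = 1
        hr, ef = hit_rate_and_ef(scores, truth, 0.01)
        assert hr == 1.0
        assert ef == pytest.approx(20.0)

    def test_fraction_one_is_self_normalizing(self):
        rng = np.random.default_rng(0)
        scores = rng.random(97)
        truth = (rng.random(97) < 0.3).astype(int)
        hr, ef = hit_rate_and_ef(scores, truth, 1.0)
        assert ef == pytest.approx(1.0)
        assert hr == pytest.approx(truth.mean())

    def test_full_tie_warns(self):
        with pytest.warns(RuntimeWarning, match="tied"):
            hit_rate_and_ef(np.ones(10), np.r_[np.ones(3), np.zeros(7)], 0.5)

    def test_no_actives_ef_nan(self):
        with pytest.warns(RuntimeWarning, match="enrichment"):
            hr, ef = hit_rate_and_ef([0.3, 0.2], [0, 0], 0.5)
        assert hr == 0.0 and math.isnan(ef)

    @given(st.integers(10, 200), st.integers(1, 9), st.integers(0, 10 ** 6))
    def test_ef_times_prevalence_is_hr(self, n, tenth, seed):
        rng = np.random.default_rng(seed)
        scores = rng.permutation(n).astype(float)
        truth = (rng.random(n) < 0.3).astype(int)
        if truth.sum() in (0, n):
            return
        frac = tenth / 10
        hr, ef = hit_rate_and_ef(scores, truth, frac)
        assert ef * truth.mean() == pytest.approx(hr, abs=1e-12)

    def test_order_permutation_invariance(self):
        rng = np.random.default_rng(4)
        scores = rng.permutation(50).astype(float)
        truth = (rng.random(50) < 0.2).astype(int)
        perm = rng.permutation(50)
        assert hit_rate_and_ef(scores, truth, 0.1) == \
            hit_rate_and_ef(scores[perm], truth[perm], 0.1)
        assert bedroc(scores, truth) == pytest.approx(
            bedroc(scores[perm], truth[perm]), abs=1e-12)


class TestRankAverage:
    def test_dominant_method_gets_top_rank(self):
        table = pd.DataFrame({"A": [0.9, 0.8, 0.7], "B": [0.5, 0.4, 0.3]})
        out = rank_average(table)
        assert out["A"] == 2.0 and out["B"] == 1.0

    def test_midrank_on_ties(self):
        table = pd.DataFrame({"A": [0.5], "B": [0.5]})
        out = rank_average(table)
        assert out["A"] == out["B"] == 1.5

    def test_three_methods_two_datasets(self):
        # per-dataset ranks {(3,2),(2,3),(1,1)} -> means {2.5, 2.5, 1.0}
        table = pd.DataFrame({"A": [0.9, 0.5], "B": [0.8, 0.6], "C": [0.1, 0.2]})
        out = rank_average(table)
        assert out.tolist() == [2.5, 2.5, 1.0]

    def test_single_method_rejected(self):
        with pytest.raises(ValueError):
            rank_average(pd.DataFrame({"A": [1.0]}))

    def test_missing_cells_dropped_with_warning(self):
        table = pd.DataFrame({"A": [0.9, np.nan], "B": [0.5, 0.4],
                              "C": [0.7, 0.6]})
        with pytest.warns(RuntimeWarning):
            out = rank_average(table)
        assert out["A"] == 3.0  # ranked only where present
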