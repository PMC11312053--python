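import numpy as np
import pytest

from pubag.augment import PUPools
from pubag.learners import (BagConfig, BaseLearnerConfig, EnsembleModel,
                            PredictionResult, fit_base, fit_baseline,
                            fit_napu_bagging, fit_pn_weighted,
                            fit_pu_bagging, fit_pu_iterative, fit_tao,
                            load_model, napu_default_bag_config, predict,
                            sample_bag, save_model)

from conftest import random_fp_matrix, toy_pools

FAST = BaseLearnerConfig(calibrate_probabilities=False)
# fixed-width kernel for limit comparisons: gamma="scale" depends on the
# training matrix, which differs between the compared fits
FIXED = BaseLearnerConfig(calibrate_probabilities=False, gamma=0.1)


def separable_xy(n=10, n_features=8, gap=3.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n, n_features))
    X[:n, 0] += gap
    y = np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)]
    return X, y


class TestFitBase:
    def test_separable_training_accuracy(self):
        X, y = separable_xy()
        clf = fit_base(X, y, cfg=FAST)
        assert (clf.predict(X) == y).all()

    def test_conflicting_duplicate_point_near_half(self):
        # one location carrying both labels -> probability ~ 0.5 there
        X = np.array([[0.0]] * 10 + [[0.0]] * 10 + [[5.0]] * 4 + [[-5.0]] * 4)
        y = np.array([1] * 10 + [0] * 10 + [1] * 4 + [0] * 4)
        clf = fit_base(X, y, cfg=BaseLearnerConfig())
        p = clf.predict_proba(np.array([[0.0]]))[0, list(clf.classes_).index(1)]
        assert abs(p - 0.5) < 0.1

    def test_weighting_equals_duplication(self):
        # doubling a class's weight must reproduce the decision function of
        # physically duplicating its samples
        X = np.array([[0.0, 0], [1.0, 0], [3.0, 0], [4.0, 0]])
        y = np.array([1, 1, 0, 0])
        w = np.array([2.0, 2.0, 1.0, 1.0])
        dup_X = np.vstack([X[:2], X])
        dup_y = np.r_[y[:2], y]
        grid = np.c_[np.linspace(-1, 5, 30), np.zeros(30)]
        f_w = fit_base(X, y, weights=w, cfg=FIXED).decision_function(grid)
        f_d = fit_base(dup_X, dup_y, cfg=FIXED).decision_function(grid)
        assert np.allclose(f_w, f_d, atol=1e-6)

    def test_single_class_errors(self):
        X = np.zeros((5, 3))
        with pytest.raises(ValueError, match="single-class"):
            fit_base(X, np.ones(5), cfg=FAST)

    def test_nonpositive_weights_rejected(self):
        X, y = separable_xy(4)
        with pytest.raises(ValueError):
            fit_base(X, y, weights=np.zeros(len(y)), cfg=FAST)


class TestNonBaggingStrategies:
    def test_baseline_needs_both_pools(self, toy):
        fps, pools = toy
        empty_neg = PUPools(pools.positives, frozenset(), frozenset(),
                            pools.unlabeled)
        with pytest.raises(ValueError):
            fit_baseline(empty_neg, fps, FAST)

    def test_tao_requires_putative(self, toy):
        fps, pools = toy
        no_put = PUPools(pools.positives, pools.true_negatives, frozenset(),
                         pools.unlabeled)
        fit_baseline(no_put, fps, FAST)  # baseline fine without putative
        with pytest.raises(ValueError):
            fit_tao(no_put, fps, FAST)

    def test_pn_weight_one_limit_matches_full_weight_training(self, toy):
        fps, pools = toy
        m = fit_pn_weighted(pools, fps, FIXED, augment_weight=1 - 1e-9)
        X = np.vstack([fps.bits[fps.positions(sorted(pools.positives))],
                       fps.bits[fps.positions(sorted(pools.true_negatives))],
                       fps.bits[fps.positions(sorted(pools.unlabeled))]]).astype(float)
        y = np.r_[np.ones(len(pools.positives)),
                  np.zeros(len(pools.true_negatives) + len(pools.unlabeled))]
        ref = fit_base(X, y, cfg=FIXED)
        grid = fps.bits.astype(float)
        assert np.allclose(m.members[0].decision_function(grid),
                           ref.decision_function(grid), atol=1e-6)

    def test_pn_weight_zero_limit_recovers_baseline(self, toy):
        fps, pools = toy
        m = fit_pn_weighted(pools, fps, FIXED, augment_weight=1e-9)
        ref = fit_baseline(pools, fps, FIXED)
        grid = fps.bits.astype(float)
        # agreement is limited by the SVM solver tolerance (1e-3), not by
        # the vanishing weight
        assert np.allclose(m.members[0].decision_function(grid),
                           ref.members[0].decision_function(grid), atol=5e-3)

    def test_pn_weight_bounds(self, toy):
        fps, pools = toy
        for w in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(ValueError):
                fit_pn_weighted(pools, fps, FAST, augment_weight=w)


class TestPuIterative:
    def test_fixed_point_terminates_in_one_round(self):
        # unlabeled identical to positives -> nothing predicted negative
        fps, pools = toy_pools(n_pos=15, n_neg=8, n_put=0, n_unl=0, seed=3)
        bits = fps.bits.copy()
        extra = bits[:10]  # copies of positives
        import numpy as np_
        from pubag.featurize import FingerprintMatrix
        all_bits = np_.vstack([bits, extra])
        ids = fps.ids + [f"u{i}" for i in range(10)]
        fps2 = FingerprintMatrix(ids, all_bits, fps.config)
        pools2 = PUPools(pools.positives, pools.true_negatives, frozenset(),
                         frozenset(f"u{i}" for i in range(10)))
        m = fit_pu_iterative(pools2, fps2, FAST)
        assert m.n_rounds == 1
        assert m.absorbed_ids == []

    def test_negative_like_unlabeled_absorbed_then_stops(self):
        fps, pools = toy_pools(n_pos=15, n_neg=10, n_put=0, n_unl=30, seed=1)
        m = fit_pu_iterative(pools, fps, FAST)
        assert len(m.absorbed_ids) > 0
        assert m.n_rounds <= len(pools.unlabeled)

    def test_max_rounds_validated(self, toy):
        fps, pools = toy
        with pytest.raises(ValueError):
            fit_pu_iterative(pools, fps, FAST, max_rounds=0)


class TestSampleBag:
    def make_pools(self, n_pos=100, n_neg=50, n_unl=300):
        pos = frozenset(f"p{i}" for i in range(n_pos))
        neg = frozenset(f"n{i}" for i in range(n_neg))
        unl = frozenset(f"u{i}" for i in range(n_unl))
        return PUPools(pos, neg, frozenset(), unl)

    def test_final_ratio_arithmetic(self):
        # P:N:U = 1:0.4:4.5 at bag size |P| = 100 -> 8 N + 92 U
        pools = self.make_pools()
        cfg = napu_default_bag_config(seed=0, n_bags=1)
        pos, nonpos = sample_bag(pools, cfg, 0)
        assert len(pos) == 100
        n_n = sum(1 for i in nonpos if i.startswith("n"))
        n_u = sum(1 for i in nonpos if i.startswith("u"))
        assert (n_n, n_u) == (8, 92)

    def test_pure_unlabeled_bag(self):
        pools = self.make_pools()
        cfg = BagConfig(n_bags=1, n_fraction=0.0, u_fraction=1.0, seed=0)
        pos, nonpos = sample_bag(pools, cfg, 0)
        assert len(nonpos) == 100
        assert all(i.startswith("u") for i in nonpos)
        assert len(set(nonpos)) == 100  # without replacement

    def test_pure_negative_bag(self):
        pools = self.make_pools(n_neg=150)
        cfg = BagConfig(n_bags=1, n_fraction=1.0, u_fraction=0.0, seed=0)
        pos, nonpos = sample_bag(pools, cfg, 0)
        assert len(nonpos) == 100
        assert all(i.startswith("n") for i in nonpos)

    def test_small_pool_sampled_with_replacement(self):
        pools = self.make_pools(n_neg=10)
        cfg = BagConfig(n_bags=1, n_fraction=1.0, u_fraction=0.0, seed=0)
        _, nonpos = sample_bag(pools, cfg, 0)
        assert len(nonpos) == 100
        assert len(set(nonpos)) <= 10

    def test_deterministic_per_seed_and_index(self):
        pools = self.make_pools()
        cfg = napu_default_bag_config(seed=11, n_bags=3)
        assert sample_bag(pools, cfg, 2) == sample_bag(pools, cfg, 2)
        assert sample_bag(pools, cfg, 1) != sample_bag(pools, cfg, 2)

    def test_empty_unlabeled_errors_when_needed(self):
        pools = PUPools(frozenset({"p1", "p2"}), frozenset({"n1"}))
        with pytest.raises(ValueError, match="unlabeled"):
            sample_bag(pools, BagConfig(n_bags=1), 0)

    def test_fraction_sum_validated(self):
        with pytest.raises(ValueError):
            BagConfig(n_fraction=0.5, u_fraction=0.6)


class _Const:
    """Stub classifier producing a fixed probability for every row."""
    classes_ = np.array([0, 1])

    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        return np.tile([1 - self.p, self.p], (len(X), 1))


class TestEnsembleAggregation:
    def test_mean_of_two_members(self):
        model = EnsembleModel([_Const(0.2), _Const(0.8)])
        fps = random_fp_matrix(3)
        res = predict(model, fps)
        assert np.allclose(res.probability, 0.5)

    def test_single_member_identity(self):
        model = EnsembleModel([_Const(0.73)])
        res = predict(model, random_fp_matrix(2))
        assert np.allclose(res.probability, 0.73)

    def test_matches_brute_force_reaggregation(self):
        rng = np.random.default_rng(0)
        members = [_Const(p) for p in rng.random(100)]
        model = EnsembleModel(members)
        fps = random_fp_matrix(5)
        res = predict(model, fps)
        expected = np.mean([m.p for m in members])
        assert np.allclose(res.probability, expected, atol=1e-12)

    def test_threshold_is_strict(self):
        model = EnsembleModel([_Const(0.75)])
        res = predict(model, random_fp_matrix(1), threshold=0.75)
        assert not res.is_hit[0]
        res = predict(model, random_fp_matrix(1), threshold=0.74)
        assert res.is_hit[0]

    def test_width_mismatch_rejected(self, toy):
        fps, pools = toy
        model = fit_baseline(pools, fps, FAST)
        with pytest.raises(ValueError, match="width"):
            predict(model, random_fp_matrix(3, n_bits=64))


class TestBaggingEnsembles:
    def test_pu_bagging_rejects_n_fraction(self, toy):
        fps, pools = toy
        with pytest.raises(ValueError):
            fit_pu_bagging(pools, fps, FAST,
                           BagConfig(n_bags=2, n_fraction=0.5, u_fraction=0.5))

    def test_napu_requires_true_negatives_for_n_fraction(self, toy):
        fps, pools = toy
        no_neg = PUPools(pools.positives, frozenset(), frozenset(),
                         pools.unlabeled)
        with pytest.raises(ValueError):
            fit_napu_bagging(no_neg, fps, FAST, napu_default_bag_config(n_bags=2))

    def test_seed_reproducibility_end_to_end(self, toy):
        fps, pools = toy
        cfg = napu_default_bag_config(seed=5, n_bags=4)
        a = fit_napu_bagging(pools, fps, FAST, cfg)
        b = fit_napu_bagging(pools, fps, FAST, cfg)
        assert a.bags == b.bags
        ra = predict(a, fps)
        rb = predict(b, fps)
        assert np.array_equal(ra.probability, rb.probability)


def test_model_save_load_round_trip(tmp_path, toy):
    fps, pools = toy
    model = fit_napu_bagging(pools, fps, FAST,
                             napu_default_bag_config(seed=1, n_bags=3))
    save_model(model, tmp_path / "model")
    back = load_model(tmp_path / "model")
    assert back.threshold == model.threshold
    assert back.feature_config == model.feature_config
    assert np.allclose(predict(back, fps).probability,
                       predict(model, fps).probability)


def test_prediction_result_alignment_checked():
    with pytest.raises(ValueError):
        PredictionResult(["a"], [0.1, 0.2], [False, False], 0.5)
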