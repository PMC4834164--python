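"""Boosting primitives, the AdaBoost-SVM trainer and the baselines."""

import numpy as np
import pytest

from pharmboost.ensemble import (
    AdaBoostSVM,
    BoostConfig,
    PlainSVM,
    RandomForestScreen,
    compute_sigma,
    learner_weight,
    load_model,
    rbf_kernel,
    train_weighted_svm,
    trim_weights,
    update_weights,
    weighted_error,
)
from pharmboost.errors import TrainingError
from pharmboost.evaluation import RankedScreen, evaluate
from pharmboost.synthetic import gen_fingerprint_samples


# ---------------------------------------------------------------------------
# kernel and sigma


def test_rbf_kernel_identity_and_closed_form(rng):
    x = rng.normal(size=7)
    assert rbf_kernel(x, x, sigma=0.3) == pytest.approx(1.0)
    sigma = 1.7
    z = np.array([sigma * np.sqrt(2.0)])
    assert rbf_kernel(np.array([0.0]), z, sigma) == pytest.approx(np.exp(-1))
    with pytest.raises(ValueError):
        rbf_kernel(x, x, sigma=0.0)


def test_rbf_kernel_decreases_with_distance():
    vals = [rbf_kernel(np.zeros(2), np.array([d, 0.0]), sigma=1.0)
            for d in (0.5, 1.0, 2.0, 5.0)]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    assert vals[-1] < 1e-5


def test_sigma_of_binary_column_is_one():
    X = np.array([[0.0], [2.0], [0.0], [2.0]])
    assert compute_sigma(X, scope="vector") == pytest.approx(1.0)
    assert compute_sigma(X, scope="entrywise") == pytest.approx(1.0)
    assert compute_sigma(X, scope="featurewise_mean") == pytest.approx(1.0)


def test_sigma_is_scale_homogeneous(rng):
    X = rng.exponential(1.0, size=(30, 8))
    for scope in ("vector", "entrywise", "featurewise_mean"):
        s1 = compute_sigma(X, scope=scope)
        s3 = compute_sigma(3.0 * X, scope=scope)
        assert s3 == pytest.approx(3.0 * s1, rel=1e-9)


def test_sigma_of_constant_matrix_clamps_with_warning():
    with pytest.warns(UserWarning, match="clamped"):
        sigma = compute_sigma(np.zeros((5, 4)))
    assert sigma == 1e-12


# ---------------------------------------------------------------------------
# boosting arithmetic


def test_weighted_error_cases():
    y = np.array([1, -1, 1, -1])
    w = np.full(4, 0.25)
    assert weighted_error(y, y, w) == 0.0
    assert weighted_error(-y, y, w) == 1.0
    pred = np.array([1, -1, -1, -1])
    assert weighted_error(pred, y, w) == pytest.approx(0.25)


def test_learner_weight_values_and_monotonicity():
    assert learner_weight(0.5) == 0.0
    assert learner_weight(0.25) == pytest.approx(0.5 * np.log(3.0))
    eps = np.linspace(0.01, 0.49, 20)
    alphas = [learner_weight(e) for e in eps]
    assert all(a > b for a, b in zip(alphas, alphas[1:]))
    # eps = 0 capped by the epsilon floor rather than diverging
    assert learner_weight(0.0) == pytest.approx(
        0.5 * np.log((1 - 1e-10) / 1e-10))
    with pytest.raises(ValueError):
        learner_weight(0.6)


def test_update_weights_all_correct_is_identity():
    w = np.array([0.1, 0.2, 0.3, 0.4])
    y = np.array([1, 1, -1, -1])
    out = update_weights(w, y, y, alpha=0.7)
    assert np.allclose(out, w)


def test_update_weights_single_error_hand_algebra():
    """Uniform quarter weights, one error, a = ln(3)/2: the wrong sample
    climbs to 1/2 and each correct one drops to 1/6."""
    w = np.full(4, 0.25)
    y = np.array([1, 1, 1, -1])
    pred = np.array([-1, 1, 1, -1])
    out = update_weights(w, pred, y, alpha=0.5 * np.log(3.0))
    assert out[0] == pytest.approx(0.5)
    assert np.allclose(out[1:], 1.0 / 6.0)
    assert out.sum() == pytest.approx(1.0)


def test_trim_weights_cumulative_rules():
    w = np.array([0.5, 0.3, 0.15, 0.05])
    assert trim_weights(w, 1.0).all()
    mask = trim_weights(w, 0.9)
    assert mask.tolist() == [True, True, True, False]
    uniform = np.full(10, 0.1)
    assert trim_weights(uniform, 0.9).sum() == 9


# ---------------------------------------------------------------------------
# weighted SVM


def test_weighted_svm_separates_two_points():
    X = np.array([[0.0], [4.0]])
    y = np.array([-1, 1])
    m = train_weighted_svm(X, y, np.array([0.5, 0.5]), sigma=1.0, cost=5.0)
    assert m.predict(X).tolist() == [-1, 1]


def test_weighted_svm_solves_xor_with_small_sigma():
    X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
    y = np.array([1, 1, -1, -1])
    m = train_weighted_svm(X, y, np.full(4, 0.25), sigma=0.3, cost=10.0)
    assert (m.predict(X) == y).all()


def test_upweighting_conflicting_point_flips_prediction():
    # duplicate coordinates with conflicting labels: the heavier label wins
    X = np.array([[0.0], [1.0], [1.0]])
    y = np.array([-1, 1, -1])
    low = train_weighted_svm(X, y, np.array([0.45, 0.10, 0.45]),
                             sigma=0.5, cost=5.0)
    high = train_weighted_svm(X, y, np.array([0.05, 0.90, 0.05]),
                              sigma=0.5, cost=5.0)
    probe = np.array([[1.0]])
    assert low.predict(probe)[0] == -1
    assert high.predict(probe)[0] == 1


def test_single_class_input_raises():
    X = np.array([[0.0], [1.0]])
    with pytest.raises(TrainingError):
        train_weighted_svm(X, np.array([1, 1]), np.array([0.5, 0.5]), 1.0, 5.0)


# ---------------------------------------------------------------------------
# AdaBoost trainer


def _separable_toy(n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0.0, 0.4, size=(n // 2, 2)),
                   rng.normal(4.0, 0.4, size=(n // 2, 2))])
    y = np.array([-1] * (n // 2) + [1] * (n // 2))
    return X, y


def test_separable_set_stops_after_one_perfect_learner():
    X, y = _separable_toy()
    res = AdaBoostSVM(X, y).fit()
    assert len(res.learners) == 1
    assert res.learners[0].train_error == 0.0
    assert res.training_error() == 0.0


def test_training_is_deterministic(tiny_synth_config):
    ds = gen_fingerprint_samples(tiny_synth_config)
    X, y = ds.train_arrays()
    r1 = AdaBoostSVM(X, y).fit()
    r2 = AdaBoostSVM(X, y).fit()
    assert len(r1.learners) == len(r2.learners)
    assert np.allclose(r1.alphas, r2.alphas)
    assert np.allclose(r1.epsilons, r2.epsilons)
    assert all(w1.model.bias == w2.model.bias
               for w1, w2 in zip(r1.learners, r2.learners))


def test_stored_learners_satisfy_epsilon_and_alpha_contract(tiny_synth_config):
    ds = gen_fingerprint_samples(tiny_synth_config)
    X, y = ds.train_arrays()
    res = AdaBoostSVM(X, y).fit()
    for w in res.learners:
        assert 0.0 <= w.train_error < 0.5
        expected = (learner_weight(w.train_error) if w.train_error > 0
                    else learner_weight(0.0))
        assert w.alpha == pytest.approx(expected)
    assert res.training_error() <= res.epsilons[0] + 1e-12


def test_margin_equals_weighted_vote_by_hand(tiny_synth_config):
    ds = gen_fingerprint_samples(tiny_synth_config)
    X, y = ds.train_arrays()
    res = AdaBoostSVM(X, y).fit()
    probe = X[:5]
    by_hand = np.zeros(5)
    for w in res.learners:
        by_hand += w.alpha * w.model.predict(probe)
    assert np.allclose(res.score_samples(probe), by_hand)
    assert set(np.unique(res.predict(probe))) <= {-1, 1}


def test_two_disagreeing_learners_follow_the_heavier_vote():
    X, y = _separable_toy()
    res = AdaBoostSVM(X, y).fit()
    w = res.learners[0]
    from pharmboost.ensemble import AdaBoostSVMResults, SVMModel, WeakLearner

    flipped = WeakLearner(
        SVMModel(w.model.support_vectors, -w.model.dual_coefs,
                 -w.model.bias, w.model.sigma, w.model.cost),
        alpha=w.alpha * 0.5, train_error=0.4, iteration=2)
    pair = AdaBoostSVMResults(res.model, [w, flipped], None, [])
    assert (pair.predict(X) == w.model.predict(X)).all()


def test_weight_history_normalised_each_iteration(rng):
    # coarse grid with conflicting duplicates: irreducible training error
    # keeps eps > 0, so every iteration performs a weight update
    X = rng.integers(0, 4, size=(120, 2)).astype(float)
    y = np.where(X[:, 0] + X[:, 1] + rng.normal(0, 1.5, 120) > 3, 1, -1)
    res = AdaBoostSVM(X, y).fit()
    sums = [h["weight_sum_after_update"] for h in res.history
            if "weight_sum_after_update" in h]
    assert sums, "expected at least one weight update"
    assert np.allclose(sums, 1.0, atol=1e-9)


def test_single_class_adaboost_raises():
    X = np.ones((10, 3))
    with pytest.raises(TrainingError):
        AdaBoostSVM(X, np.ones(10, int)).fit()


def test_cascade_mode_trains_and_scores(tiny_synth_config):
    ds = gen_fingerprint_samples(tiny_synth_config)
    X, y = ds.train_arrays()
    res = AdaBoostSVM(X, y, mode="cascade", n_iterations=2,
                      max_learners_per_layer=3).fit()
    assert res.layers is not None and len(res.layers) >= 1
    Xte, yte = ds.test_arrays()
    scores = res.score_samples(Xte)
    assert scores.shape == (len(yte),)
    assert evaluate(RankedScreen(scores, yte)).auc > 0.5
    res2 = AdaBoostSVM(X, y, mode="cascade", n_iterations=2,
                       max_learners_per_layer=3).fit()
    assert np.allclose(res2.score_samples(Xte[:20]), scores[:20])


def test_per_feature_weak_learner_mode():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(60, 4))
    y = np.where(X[:, 2] > 0, 1, -1)
    res = AdaBoostSVM(X, y, weak_learner="per_feature", n_iterations=2).fit()
    assert all(w.feature_subset is not None for w in res.learners)
    assert res.learners[0].feature_subset[0] == 2
    assert res.training_error() < 0.2


def test_serialization_round_trip(tmp_path, tiny_synth_config):
    ds = gen_fingerprint_samples(tiny_synth_config)
    X, y = ds.train_arrays()
    Xte, _ = ds.test_arrays()
    res = AdaBoostSVM(X, y).fit()
    res.save(tmp_path / "model.json")
    loaded = load_model(tmp_path / "model.json")
    assert np.allclose(loaded.score_samples(Xte), res.score_samples(Xte))

    svm = PlainSVM(X, y).fit()
    svm.save(tmp_path / "svm.json")
    loaded_svm = load_model(tmp_path / "svm.json")
    assert np.allclose(loaded_svm.score_samples(Xte), svm.score_samples(Xte))


def test_summary_mentions_learners_and_error(tiny_synth_config):
    ds = gen_fingerprint_samples(tiny_synth_config)
    X, y = ds.train_arrays()
    res = AdaBoostSVM(X, y).fit()
    text = res.summary()
    assert "AdaBoost-SVM" in text
    assert "training error" in text
    assert f"learners: {len(res.learners)}" in text


def test_boost_config_validation():
    with pytest.raises(ValueError):
        BoostConfig(n_iterations=0)
    with pytest.raises(ValueError):
        BoostConfig(weight_trim_rate=0.0)
    with pytest.raises(ValueError):
        BoostConfig(sigma_mode="nonsense")


# ---------------------------------------------------------------------------
# baselines


def test_baselines_fit_separable_toy_perfectly():
    X, y = _separable_toy()
    svm = PlainSVM(X, y).fit()
    rf = RandomForestScreen(X, y, n_trees=50).fit()
    assert svm.training_error() == 0.0
    assert rf.training_error() == 0.0
    assert svm.predict(X).tolist() == y.tolist()


def test_plain_svm_fixed_sigma_mode_uses_table_value():
    X, y = _separable_toy()
    res = PlainSVM(X, y, sigma_mode="fixed").fit()
    assert res.sigma == 0.001


def test_random_forest_score_is_tree_vote_fraction(tiny_synth_config):
    ds = gen_fingerprint_samples(tiny_synth_config)
    X, y = ds.train_arrays()
    res = RandomForestScreen(X, y, n_trees=100, seed=1).fit()
    s = res.score_samples(X[:10])
    assert np.all((0.0 <= s) & (s <= 1.0))
    # scores are multiples of 1/n_trees
    assert np.allclose(np.round(s * 100), s * 100, atol=1e-9)


def test_random_forest_auc_stable_across_seeds(tiny_synth_config):
    ds = gen_fingerprint_samples(tiny_synth_config)
    X, y = ds.train_arrays()
    Xte, yte = ds.test_arrays()
    aucs = []
    for seed in (0, 1):
        res = RandomForestScreen(X, y, n_trees=1000, seed=seed).fit()
        aucs.append(evaluate(RankedScreen(res.score_samples(Xte), yte)).auc)
    assert abs(aucs[0] - aucs[1]) < 0.05
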