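"""AdaBoost.R2 components: weak tree, loss laws, weights, weighted
median, full fit, and the independent reference-implementation oracle."""

import numpy as np
import pytest
from sklearn.ensemble import AdaBoostRegressor
from sklearn.tree import DecisionTreeRegressor

from pgms import boosting
from pgms.boosting import (
    BoostingStop,
    TrainingSet,
    average_loss,
    confidence_beta,
    fit_adaboost_r2,
    fit_weighted_tree,
    loss_function,
    predict_glucose,
    update_weights,
    weighted_median_predict,
)
from pgms.tree import RegressionTree


# ---------------------------------------------------------------------------
# weak learner
# ---------------------------------------------------------------------------

def test_tree_constant_targets_single_leaf():
    tree = RegressionTree(max_depth=5).fit([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])
    assert tree.n_nodes == 1
    assert np.all(tree.predict([0.0, 2.5, 99.0]) == 4.0)


def test_tree_degenerate_features_single_leaf():
    tree = RegressionTree(max_depth=5).fit([2.0, 2.0, 2.0], [1.0, 3.0, 5.0])
    assert tree.n_nodes == 1
    assert tree.predict([2.0])[0] == pytest.approx(3.0)


def test_tree_depth1_matches_exhaustive_split_oracle(rng):
    """Depth-1 split threshold and leaf means equal the exhaustive
    weighted-SSE search over all midpoints."""
    for _ in range(20):
        n = rng.randint(4, 9)
        x = np.sort(rng.uniform(0, 10, n) + np.arange(n) * 1e-3)
        y = rng.uniform(-5, 5, n)
        w = rng.uniform(0.1, 2.0, n)
        tree = RegressionTree(max_depth=1).fit(x, y, w)
        best_sse, best_thr = np.inf, None
        for p in range(1, n):
            thr = 0.5 * (x[p - 1] + x[p])
            lm = np.average(y[:p], weights=w[:p])
            rm = np.average(y[p:], weights=w[p:])
            sse = np.sum(w[:p] * (y[:p] - lm) ** 2) + np.sum(
                w[p:] * (y[p:] - rm) ** 2
            )
            if sse < best_sse - 1e-12:
                best_sse, best_thr = sse, thr
        left = np.average(y[x <= best_thr], weights=w[x <= best_thr])
        right = np.average(y[x > best_thr], weights=w[x > best_thr])
        probe_lo, probe_hi = best_thr - 1e-6, best_thr + 1e-6
        assert tree.predict([probe_lo])[0] == pytest.approx(left, abs=1e-9)
        assert tree.predict([probe_hi])[0] == pytest.approx(right, abs=1e-9)


def test_deep_tree_interpolates_distinct_points(rng):
    x = rng.permutation(np.linspace(0, 100, 64))
    y = rng.uniform(-10, 10, 64)
    tree = RegressionTree(max_depth=20).fit(x, y)
    assert np.allclose(tree.predict(x), y)


def test_fit_weighted_tree_zero_weight_ignores_points():
    data = TrainingSet([1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 100.0, 100.0])
    w = np.array([0.5, 0.5, 0.0, 0.0])
    tree = fit_weighted_tree(data, weights=w, max_depth=3)
    assert tree.predict([3.5])[0] == pytest.approx(0.0)


def test_tree_serialization_roundtrip(rng):
    x = rng.uniform(0, 50, 30)
    y = rng.uniform(-5, 5, 30)
    tree = RegressionTree(max_depth=4).fit(x, y)
    clone = RegressionTree.from_dict(tree.to_dict())
    probe = rng.uniform(0, 50, 100)
    assert np.array_equal(tree.predict(probe), clone.predict(probe))


# ---------------------------------------------------------------------------
# boosting primitives
# ---------------------------------------------------------------------------

def test_loss_function_forced_values():
    den = 3.5
    l = np.array([den])
    assert loss_function(l, den, "linear")[0] == pytest.approx(1.0)
    assert loss_function(l, den, "square")[0] == pytest.approx(1.0)
    assert loss_function(l, den, "exponential")[0] == pytest.approx(1 - np.exp(-1))
    zero = np.zeros(3)
    for kind in boosting.LOSS_KINDS:
        assert np.all(loss_function(zero, den, kind) == 0.0)


def test_loss_function_random_matches_formulas(rng):
    l = rng.uniform(0, 10, 100)
    den = float(l.max())
    assert np.allclose(loss_function(l, den, "linear"), l / den, atol=1e-12)
    assert np.allclose(loss_function(l, den, "square"), (l / den) ** 2, atol=1e-12)
    assert np.allclose(
        loss_function(l, den, "exponential"), 1 - np.exp(-l / den), atol=1e-12
    )
    for kind in boosting.LOSS_KINDS:
        out = loss_function(l, den, kind)
        assert np.all((out >= 0) & (out <= 1))


def test_loss_function_zero_den_gives_zero_losses():
    assert np.all(loss_function([1.0, 2.0], 0.0, "linear") == 0.0)


def test_average_loss_cases(rng):
    assert average_loss(np.zeros(4), np.full(4, 0.25)) == 0.0
    assert average_loss([0.0, 1.0], [0.5, 0.5]) == pytest.approx(0.5)
    L = rng.uniform(0, 1, 50)
    D = rng.dirichlet(np.ones(50))
    assert average_loss(L, D) == pytest.approx(float(sum(L * D)), abs=1e-12)


def test_confidence_beta():
    assert confidence_beta(0.25) == pytest.approx(1.0 / 3.0)
    assert confidence_beta(0.0) == boosting.BETA_MIN  # clamp on perfect round
    with pytest.raises(BoostingStop):
        confidence_beta(0.5)
    for avg in np.linspace(0.01, 0.49, 20):
        assert confidence_beta(avg) == pytest.approx(avg / (1 - avg))


def test_update_weights_factors_and_normalization(rng):
    D = np.full(3, 1 / 3)
    L = np.array([1.0, 0.0, 0.5])
    out = update_weights(D, 0.5, L, alpha=1.0)
    # pre-normalization factors: beta^0 = 1 (hardest kept), beta^1 = 0.5
    raw = D * np.array([1.0, 0.5, 0.5**0.5])
    assert np.allclose(out, raw / raw.sum())
    assert out.sum() == pytest.approx(1.0, abs=1e-12)
    # random inputs stay a distribution proportional to the raw update
    D = rng.dirichlet(np.ones(30))
    L = rng.uniform(0, 1, 30)
    beta, alpha = 0.37, 0.42
    out = update_weights(D, beta, L, alpha)
    raw = D * beta ** (alpha * (1 - L))
    assert np.allclose(out, raw / raw.sum(), atol=1e-12)
    assert out.sum() == pytest.approx(1.0, abs=1e-12)


def test_update_weights_alpha1_reduces_to_classical(rng):
    """With alpha = 1 the learning-rate update is the classical
    AdaBoost.R2 reweighting D * beta**(1 - L), renormalized."""
    D = rng.dirichlet(np.ones(20))
    L = rng.uniform(0, 1, 20)
    beta = 0.2
    classical = D * beta ** (1.0 - L)
    classical /= classical.sum()
    assert np.allclose(update_weights(D, beta, L, alpha=1.0), classical, atol=1e-12)


# ---------------------------------------------------------------------------
# weighted median
# ---------------------------------------------------------------------------

def _constant_model(preds, betas, alpha=1.0):
    rounds = [
        boosting.BoostRound(
            tree=RegressionTree(max_depth=1).fit([0.0, 1.0], [p, p]),
            beta=b,
            avg_loss=b / (1 + b),
            den=1.0,
        )
        for p, b in zip(preds, betas)
    ]
    return boosting.EnsembleModel(rounds=rounds, alpha=alpha, loss_kind="linear", seed=0)


def _bruteforce_weighted_median(preds, betas, alpha):
    """Direct evaluation of the inf over candidate values."""
    w = alpha * np.log(1.0 / np.asarray(betas))
    half = 0.5 * w.sum()
    for v in sorted(preds):
        if sum(wt for p, wt in zip(preds, w) if p <= v) >= half:
            return v
    raise AssertionError("no candidate reached half the weight")


def test_weighted_median_trivials():
    assert weighted_median_predict(_constant_model([7.0], [0.3]), 5.0) == 7.0
    assert weighted_median_predict(_constant_model([4.0] * 5, [0.1] * 5), 5.0) == 4.0


def test_weighted_median_matches_bruteforce_inf(rng):
    for _ in range(50):
        T = rng.randint(1, 9)
        preds = list(rng.uniform(-50, 50, T))
        betas = list(rng.uniform(1e-3, 0.99, T))
        alpha = float(rng.uniform(0.01, 1.0))
        model = _constant_model(preds, betas, alpha)
        got = weighted_median_predict(model, 0.5)
        assert got == pytest.approx(
            _bruteforce_weighted_median(preds, betas, alpha), abs=1e-9
        )
        assert min(preds) <= got <= max(preds)


def test_weighted_median_permutation_invariant(rng):
    preds = list(rng.uniform(-20, 20, 6))
    betas = list(rng.uniform(0.05, 0.9, 6))
    base = weighted_median_predict(_constant_model(preds, betas), 1.0)
    for _ in range(5):
        perm = rng.permutation(6)
        shuffled = _constant_model(
            [preds[i] for i in perm], [betas[i] for i in perm]
        )
        assert weighted_median_predict(shuffled, 1.0) == base


# ---------------------------------------------------------------------------
# full fit
# ---------------------------------------------------------------------------

def test_fit_constant_difference_predicts_it_exactly(rng):
    x = rng.uniform(50, 300, 40)
    model = fit_adaboost_r2(
        TrainingSet(x, np.full(40, 12.5)), max_depth=3, n_estimators=10, seed=1
    )
    assert np.all(boosting.predict_difference(model, x) == 12.5)
    assert np.all(predict_glucose(model, x) == x + 12.5)


def test_fit_determinism(rng):
    x = rng.uniform(50, 300, 80)
    d = 0.2 * x - 20 + rng.normal(0, 3, 80)
    probe = rng.uniform(50, 300, 50)
    a = fit_adaboost_r2(TrainingSet(x, d), max_depth=5, n_estimators=20, seed=3)
    b = fit_adaboost_r2(TrainingSet(x, d), max_depth=5, n_estimators=20, seed=3)
    assert np.array_equal(
        weighted_median_predict(a, probe), weighted_median_predict(b, probe)
    )
    assert np.array_equal(a.betas, b.betas)


def test_fit_invariants(rng):
    x = rng.uniform(50, 300, 100)
    d = 0.3 * x - 30 + rng.normal(0, 5, 100)
    model = fit_adaboost_r2(
        TrainingSet(x, d), max_depth=4, n_estimators=30, alpha=0.7,
        loss_kind="exponential", seed=2,
    )
    assert model.T >= 1
    assert np.all((model.betas > 0) & (model.betas < 1))
    assert all(r.avg_loss < 0.5 for r in model.rounds)
    # weighted median bounded by the per-round extremes
    probe = rng.uniform(50, 300, 30)
    rounds = model.round_predictions(probe)
    med = weighted_median_predict(model, probe)
    assert np.all(med >= rounds.min(axis=0) - 1e-12)
    assert np.all(med <= rounds.max(axis=0) + 1e-12)


def test_monotone_noiseless_difference_recovered(rng):
    """A deterministic monotone d(x) is learned to under 1 % MARD."""
    x = np.sort(rng.uniform(60, 350, 300))
    d = 0.6 * x - 60 + 15 * np.sin(x / 50)
    model = fit_adaboost_r2(
        TrainingSet(x, d), max_depth=10, n_estimators=200, alpha=0.7, seed=1
    )
    z = predict_glucose(model, x)
    y = x + d
    from pgms.metrics import mard

    assert mard(y, z) < 1.0


def test_predict_glucose_clips_to_physiological_range():
    x = np.array([30.0, 40.0])
    model = fit_adaboost_r2(
        TrainingSet(x, np.array([-25.0, -25.0])), max_depth=1, n_estimators=5, seed=0
    )
    z = predict_glucose(model, np.array([22.0]))
    assert z[0] == boosting.GLUCOSE_CLIP[0]


def test_model_json_roundtrip(rng):
    x = rng.uniform(50, 300, 60)
    d = 0.2 * x - 10 + rng.normal(0, 2, 60)
    model = fit_adaboost_r2(TrainingSet(x, d), max_depth=4, n_estimators=15, seed=5)
    clone = boosting.EnsembleModel.from_json(model.to_json())
    probe = rng.uniform(50, 300, 40)
    assert np.array_equal(
        weighted_median_predict(model, probe), weighted_median_predict(clone, probe)
    )


def test_alpha1_matches_reference_implementation(rng):
    """With alpha = 1 and the same weak learner, predictions agree with
    the scikit-learn AdaBoost.R2 regressor on a random grid."""
    x = rng.uniform(50, 400, 120)
    d = 0.3 * x - 40 + 10 * np.sin(x / 40) + rng.normal(0, 5, 120)
    grid = np.linspace(50, 400, 400)
    for loss in boosting.LOSS_KINDS:
        sk = AdaBoostRegressor(
            estimator=DecisionTreeRegressor(max_depth=3),
            n_estimators=25,
            learning_rate=1.0,
            loss=loss,
            random_state=7,
        ).fit(x[:, None], d)
        mine = fit_adaboost_r2(
            TrainingSet(x, d), max_depth=3, n_estimators=25, alpha=1.0,
            loss_kind=loss, seed=7,
        )
        agree = np.mean(
            np.abs(sk.predict(grid[:, None]) - weighted_median_predict(mine, grid))
            <= 1e-6
        )
        assert agree >= 0.95
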