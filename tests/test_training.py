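"""Tests for the hybrid PSO + gradient-descent training machinery."""
import numpy as np
import pytest

import fwnnet as fw
from fwnnet import A_MIN, SIGMA_MIN, NetworkConfig, PSOConfig, TrainingConfig
from fwnnet.training import (
    analytic_gradients,
    batch_gradients,
    gradient_step,
    hybrid_train,
    loss,
    pso_optimize,
)

from conftest import random_params, scalar_forward


@pytest.mark.parametrize("pred, true, expected", [
    (2.0, 2.0, 0.0),
    (0.0, 2.0, 2.0),
    (1.5, 1.0, 0.125),
])
def test_loss(pred, true, expected):
    assert loss(pred, true) == pytest.approx(expected)


def test_gradient_zero_at_perfect_fit(rng):
    cfg = NetworkConfig(n=2, M=2, N_k=2)
    params = random_params(cfg, rng)
    x = rng.uniform(-1, 1, 2)
    y = fw.forward(x, params, cfg).y
    grads = analytic_gradients(x, y, params, cfg)
    for g in grads.values():
        np.testing.assert_allclose(g, 0.0, atol=1e-12)


def test_gradient_ybar_single_rule(rng):
    """With one rule and zero weights, y = ybar so dE/dybar = y_pred - y_true."""
    cfg = NetworkConfig(n=2, M=1, N_k=2)
    params = random_params(cfg, rng)
    params.w[:] = 0.0
    x = rng.uniform(-1, 1, 2)
    y_true = 0.3
    grads = analytic_gradients(x, y_true, params, cfg)
    assert grads["ybar"][0] == pytest.approx(params.ybar[0] - y_true)


def _fd_gradient(x, y_true, params, cfg, group, idx, h=1e-6):
    def eval_at(delta):
        p = params.copy()
        getattr(p, group)[idx] += delta
        return 0.5 * (y_true - scalar_forward(x, p, cfg)) ** 2
    return (eval_at(h) - eval_at(-h)) / (2 * h)


def test_gradients_match_finite_differences(rng):
    """Analytic gradients agree with central differences on the independent
    scalar-forward oracle for every parameter group (spot check; the full
    50-draw sweep runs in the acceptance suite)."""
    for normalize in (False, True):
        cfg = NetworkConfig(n=2, M=2, N_k=2, normalize_wavelet=normalize)
        for _ in range(5):
            params = random_params(cfg, rng)
            x = rng.uniform(-2, 2, 2)
            y_true = float(rng.uniform(-1, 1))
            grads = analytic_gradients(x, y_true, params, cfg)
            for group in fw.FWNNetParameters.GROUPS:
                arr = grads[group]
                for idx in np.ndindex(arr.shape):
                    fd = _fd_gradient(x, y_true, params, cfg, group, idx)
                    assert arr[idx] == pytest.approx(fd, rel=1e-5, abs=1e-9)


def test_batch_gradient_is_mean_of_singles(rng):
    cfg = NetworkConfig(n=2, M=2, N_k=2)
    params = random_params(cfg, rng)
    X = rng.uniform(-1, 1, (4, 2))
    t = rng.uniform(-1, 1, 4)
    batch = batch_gradients(X, t, params, cfg)
    for group in fw.FWNNetParameters.GROUPS:
        singles = np.mean([analytic_gradients(X[i], t[i], params, cfg)[group]
                           for i in range(4)], axis=0)
        np.testing.assert_allclose(batch[group], singles, rtol=1e-12)


def test_gradient_step_projections(rng):
    cfg = NetworkConfig(n=1, M=1, N_k=1)
    params = random_params(cfg, rng)
    params.a[:] = 0.05
    params.sigma[:] = 0.05
    zeros = {g: np.zeros_like(getattr(params, g))
             for g in fw.FWNNetParameters.GROUPS}
    tc = TrainingConfig(gamma_ybar=0.1)

    stepped = gradient_step(params, zeros, tc)
    for g in fw.FWNNetParameters.GROUPS:
        np.testing.assert_array_equal(getattr(stepped, g), getattr(params, g))

    grads = {g: np.zeros_like(v) for g, v in zeros.items()}
    grads["ybar"] = np.ones_like(params.ybar)
    stepped = gradient_step(params, grads, tc)
    assert stepped.ybar[0] == pytest.approx(params.ybar[0] - 0.1)

    # a dilation update crossing zero is projected to sign-preserving A_MIN
    grads = {g: np.zeros_like(v) for g, v in zeros.items()}
    grads["a"] = np.full_like(params.a, 5.05)  # lands at -5e-4, inside floor
    stepped = gradient_step(params, grads, tc)
    assert stepped.a[0, 0, 0] == pytest.approx(-A_MIN)

    grads = {g: np.zeros_like(v) for g, v in zeros.items()}
    grads["sigma"] = np.full_like(params.sigma, 100.0)
    stepped = gradient_step(params, grads, tc)
    assert stepped.sigma[0, 0] == pytest.approx(SIGMA_MIN)


# ---------------------------------------------------------------------------
# PSO
# ---------------------------------------------------------------------------

def _sphere(v):
    return float(np.sum(v * v))


def test_pso_sphere():
    cfg = PSOConfig(psize=20, maxgen=50, rng_seed=0, mode="plain_pso")
    res = pso_optimize(_sphere, -np.ones(5) * 5, np.ones(5) * 5, cfg)
    assert res.best_fitness < 1e-2
    assert np.all(np.diff(res.history) <= 0)


def test_pso_inline_blocks_and_monotonicity():
    cfg = PSOConfig(psize=10, maxgen=30, rng_seed=0, mode="inline_pso")
    blocks = [np.arange(0, 2), np.arange(2, 5)]
    res = pso_optimize(_sphere, -np.ones(5) * 5, np.ones(5) * 5, cfg,
                       blocks=blocks)
    assert np.all(np.diff(res.history) <= 0)
    assert res.best_fitness < 0.5


def test_pso_maxgen_one_returns_best_initial():
    cfg = PSOConfig(psize=8, maxgen=1, rng_seed=7, mode="plain_pso")
    rng = np.random.default_rng(7)
    lo, hi = -np.ones(3), np.ones(3)
    init = rng.uniform(lo, hi, (8, 3))
    res = pso_optimize(_sphere, lo, hi, cfg)
    assert res.best_fitness == pytest.approx(
        min(_sphere(p) for p in init))
    assert res.history.size == 1


def test_pso_determinism():
    cfg = PSOConfig(psize=10, maxgen=20, rng_seed=5)
    blocks = [np.arange(0, 3), np.arange(3, 5)]
    r1 = pso_optimize(_sphere, -np.ones(5), np.ones(5), cfg, blocks=blocks)
    r2 = pso_optimize(_sphere, -np.ones(5), np.ones(5), cfg, blocks=blocks)
    np.testing.assert_array_equal(r1.best_position, r2.best_position)
    np.testing.assert_array_equal(r1.history, r2.history)


def test_pso_all_nonfinite_raises():
    cfg = PSOConfig(psize=5, maxgen=5, rng_seed=0)
    with pytest.raises(RuntimeError):
        pso_optimize(lambda v: np.inf, -np.ones(2), np.ones(2), cfg)


# ---------------------------------------------------------------------------
# Hybrid training
# ---------------------------------------------------------------------------

def test_hybrid_single_pair_bias_converges():
    """One training pair, one rule, weights pinned at zero: the rule bias
    must converge to the target (its closed-form optimum)."""
    cfg = NetworkConfig(n=1, M=1, N_k=1)
    X = np.array([[0.4]])
    t = np.array([1.7])
    tc = TrainingConfig(max_epochs=2000, gamma_ybar=0.05, gamma_w=1e-9)
    pc = PSOConfig(psize=5, maxgen=5, rng_seed=0,
                   position_bounds={"w": (0.0, 0.0)})
    params, trace = hybrid_train(X, t, cfg, tc, pc, standardize=False)
    assert params.w[0, 0] == pytest.approx(0.0, abs=1e-6)
    assert fw.forward(X[0], params, cfg).y == pytest.approx(t[0], abs=1e-3)
    assert params.ybar[0] == pytest.approx(t[0], abs=1e-3)


def test_hybrid_empty_dataset():
    cfg = NetworkConfig(n=2)
    with pytest.raises(ValueError):
        hybrid_train(np.empty((0, 2)), np.empty(0), cfg)


def test_hybrid_deterministic_trace():
    X, y = fw.generate_class_dataset(10, seed=4)
    cfg = NetworkConfig(n=4, M=2, N_k=2, num_classes=4)
    tc = TrainingConfig(max_epochs=20, rng_seed=4)
    pc = PSOConfig(psize=8, maxgen=10, rng_seed=4)
    p1, tr1 = hybrid_train(X, y.astype(float), cfg, tc, pc)
    p2, tr2 = hybrid_train(X, y.astype(float), cfg, tc, pc)
    np.testing.assert_array_equal(tr1.pso_best_fitness, tr2.pso_best_fitness)
    np.testing.assert_array_equal(tr1.train_rmse, tr2.train_rmse)
    for g in fw.FWNNetParameters.GROUPS:
        np.testing.assert_array_equal(getattr(p1, g), getattr(p2, g))


def test_full_batch_rmse_mostly_nonincreasing():
    """With small rates on a fixed batch, the full-batch RMSE decreases over
    at least 90% of consecutive epochs."""
    X, y = fw.generate_class_dataset(25, seed=9)
    cfg = NetworkConfig(n=4, M=2, N_k=2, num_classes=4)
    r = 0.005
    tc = TrainingConfig(max_epochs=150, rng_seed=9, gamma_c=r, gamma_sigma=r,
                        gamma_b=r, gamma_a=r, gamma_w=r, gamma_ybar=r)
    pc = PSOConfig(psize=10, maxgen=10, rng_seed=9)
    _, trace = hybrid_train(X, y.astype(float), cfg, tc, pc)
    diffs = np.diff(trace.train_rmse)
    frac_nonincreasing = np.mean(diffs <= 1e-12)
    assert frac_nonincreasing >= 0.9


def test_hybrid_beats_plain_gd_majority():
    """PSO-initialized training reaches a training RMSE at least as low as
    plain gradient descent from a random start on most seeded datasets."""
    wins = 0
    n_seeds = 10
    for seed in range(n_seeds):
        X, y = fw.generate_class_dataset(15, seed=seed)
        t = y.astype(float)
        cfg = NetworkConfig(n=4, M=2, N_k=2, num_classes=4)
        tc = TrainingConfig(max_epochs=60, rng_seed=seed)
        pc = PSOConfig(psize=15, maxgen=20, rng_seed=seed)
        _, hybrid_trace = hybrid_train(X, t, cfg, tc, pc)

        # plain GD: random init inside the same box, same epoch budget
        rng = np.random.default_rng(seed)
        Xs = (X - X.mean(0)) / X.std(0)
        params = fw.FWNNetParameters.random(
            cfg, rng, feature_low=Xs.min(0), feature_high=Xs.max(0),
            wy_bound=3.0)
        try:
            for _ in range(tc.max_epochs):
                grads = batch_gradients(Xs, t, params, cfg)
                params = fw.gradient_step(params, grads, tc)
            plain_rmse = fw.rmse(Xs, t, params, cfg)
        except fw.DegenerateInputError:
            plain_rmse = np.inf  # random start left no rule active
        if hybrid_trace.train_rmse[-1] <= plain_rmse + 1e-9:
            wins += 1
    assert wins >= 7, f"hybrid won only {wins}/{n_seeds}"
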