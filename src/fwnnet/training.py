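"""Hybrid FWNNet training: PSO initialization followed by gradient descent.

The squared-error loss E = 1/2 (y_true - y_pred)^2 is minimized in two
stages.  A small particle swarm (global-best, linearly decreasing inertia)
first searches the parameter box for a good starting point — either over the
full concatenated parameter vector ("plain_pso") or blockwise over the
(c, sigma), (b, a), (w, ybar) groups in sequence within each generation
("inline_pso").  Gradient descent with per-group learning rates then refines
the swarm's best position; the gradients are the exact chain-rule derivatives
through the eight network layers.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .config import A_MIN, EPS_DEN, SIGMA_MIN, PSOConfig, TrainingConfig
from .model import (
    DegenerateInputError,
    FWNNetParameters,
    NetworkConfig,
    _batch_layers,
    batch_forward,
    mother_wavelet,
    mother_wavelet_derivative,
)


def loss(y_pred: float, y_true: float) -> float:
    """Per-sample squared error E = 1/2 (y_true - y_pred)^2."""
    return 0.5 * float(y_true - y_pred) ** 2


def rmse(X, t, params: FWNNetParameters, config: NetworkConfig) -> float:
    """Dataset root-mean-square error sqrt(mean (y - t)^2)."""
    y = batch_forward(np.asarray(X, float), params, config)
    return float(np.sqrt(np.mean((y - np.asarray(t, float)) ** 2)))


# ---------------------------------------------------------------------------
# Analytic gradients
# ---------------------------------------------------------------------------

def _prod_except(arr: np.ndarray) -> np.ndarray:
    """prod over the last axis excluding each element (zero-safe)."""
    n = arr.shape[-1]
    left = np.ones_like(arr)
    right = np.ones_like(arr)
    if n > 1:
        np.cumprod(arr[..., :-1], axis=-1, out=left[..., 1:])
        rev = np.cumprod(arr[..., :0:-1], axis=-1)
        right[..., :-1] = rev[..., ::-1]
    return left * right


def batch_gradients(X, t, params: FWNNetParameters, config: NetworkConfig
                    ) -> dict:
    """Mean over the batch of per-sample gradients dE/dTheta.

    Returns a dict keyed by parameter group with arrays shaped like the
    corresponding parameter.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float)
    B = X.shape[0]
    z, psi, Psi, u, mu, O, Y, den, y = _batch_layers(X, params, config)
    if np.any(den <= EPS_DEN) or not np.all(np.isfinite(y)):
        raise DegenerateInputError("all rules inactive for some sample")

    r = (y - t)[:, None]                      # dE/dy, broadcast over rules
    dY = r * O / den[:, None]                 # (B, M)
    dO = r * (Y - y[:, None]) / den[:, None]  # (B, M)

    d_ybar = dY
    d_w = dY[:, :, None] * Psi                               # (B, M, N)
    dPsi = dY[:, :, None] * params.w[None]                   # (B, M, N)
    dpsi = dPsi[..., None] * _prod_except(psi)               # (B, M, N, n)

    wave_prime = mother_wavelet_derivative(z, config.wavelet_family)
    if config.normalize_wavelet:
        norm = 1.0 / np.sqrt(np.abs(params.a))[None]
        wave = mother_wavelet(z, config.wavelet_family)
        dnorm_da = (-0.5 * np.sign(params.a)
                    * np.abs(params.a) ** -1.5)[None]
        d_b = dpsi * norm * wave_prime * (-1.0 / params.a[None])
        d_a = dpsi * (norm * wave_prime * (-z / params.a[None])
                      + dnorm_da * wave)
    else:
        d_b = dpsi * wave_prime * (-1.0 / params.a[None])
        d_a = dpsi * wave_prime * (-z / params.a[None])

    dmu = dO[:, :, None] * _prod_except(mu)                  # (B, M, n)
    common = dmu * mu * 2.0 * u / params.sigma[None]
    d_c = common
    d_sigma = common * u

    return {
        "c": d_c.mean(axis=0), "sigma": d_sigma.mean(axis=0),
        "b": d_b.mean(axis=0), "a": d_a.mean(axis=0),
        "w": d_w.mean(axis=0), "ybar": d_ybar.mean(axis=0),
    }


def analytic_gradients(x, y_true: float, params: FWNNetParameters,
                       config: NetworkConfig) -> dict:
    """Exact single-sample gradients dE/dTheta for E = 1/2 (y_true - y)^2."""
    x = np.asarray(x, dtype=float)
    return batch_gradients(x[None, :], np.asarray([y_true], float),
                           params, config)


def gradient_step(params: FWNNetParameters, gradients: dict,
                  train_config: TrainingConfig) -> FWNNetParameters:
    """One descent step Theta <- Theta - gamma_g dE/dTheta per group,
    with sigma and |a| projected back onto their floors."""
    rates = train_config.rates()
    new = params.copy()
    for g in FWNNetParameters.GROUPS:
        arr = getattr(new, g)
        arr -= rates[g] * gradients[g]
    new.sigma = np.maximum(new.sigma, SIGMA_MIN)
    # sign-preserving dilation floor; a step crossing zero keeps the old sign
    sign = np.sign(new.a)
    sign = np.where(sign == 0, np.sign(params.a), sign)
    sign = np.where(sign == 0, 1.0, sign)
    new.a = sign * np.maximum(np.abs(new.a), A_MIN)
    return new


# ---------------------------------------------------------------------------
# Particle swarm optimization
# ---------------------------------------------------------------------------

@dataclass
class PSOResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # global-best fitness after each generation


def pso_optimize(objective: Callable[[np.ndarray], float],
                 lo, hi, pso_config: PSOConfig,
                 blocks: Optional[Sequence[np.ndarray]] = None) -> PSOResult:
    """Global-best PSO over the box [lo, hi].

    Velocities are clamped to half the box width per dimension and the
    inertia weight decreases linearly from ``w_start`` to ``w_end`` over the
    generations.  In ``inline_pso`` mode the swarm moves one coordinate
    block at a time, in the given order, within every generation
    (``blocks`` = index arrays partitioning the dimensions); ``plain_pso``
    moves the full vector at once.  ``maxgen == 1`` returns the best of the
    initial population.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    D = lo.size
    cfg = pso_config
    rng = np.random.default_rng(cfg.rng_seed)
    vmax = 0.5 * (hi - lo)

    def fit(xs: np.ndarray) -> np.ndarray:
        vals = np.array([objective(p) for p in xs], dtype=float)
        vals[~np.isfinite(vals)] = np.inf
        return vals

    pos = rng.uniform(lo, hi, (cfg.psize, D))
    vel = rng.uniform(-vmax, vmax, (cfg.psize, D))
    f = fit(pos)
    if not np.any(np.isfinite(f)):
        raise RuntimeError("PSO initialization failed: objective non-finite "
                           "on every initial particle")
    pbest, pbest_f = pos.copy(), f.copy()
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
    history = [gbest_f]

    if cfg.mode == "plain_pso" or blocks is None:
        blocks = [np.arange(D)]

    for gen in range(1, cfg.maxgen):
        frac = gen / (cfg.maxgen - 1) if cfg.maxgen > 1 else 0.0
        wt = cfg.w_start - (cfg.w_start - cfg.w_end) * frac
        for idx in blocks:
            r1 = rng.random((cfg.psize, idx.size))
            r2 = rng.random((cfg.psize, idx.size))
            vel[:, idx] = (wt * vel[:, idx]
                           + cfg.c1 * r1 * (pbest[:, idx] - pos[:, idx])
                           + cfg.c2 * r2 * (gbest[None, idx] - pos[:, idx]))
            vel[:, idx] = np.clip(vel[:, idx], -vmax[idx], vmax[idx])
            pos[:, idx] = np.clip(pos[:, idx] + vel[:, idx], lo[idx], hi[idx])
            f = fit(pos)
            better = f < pbest_f
            pbest[better] = pos[better]
            pbest_f[better] = f[better]
            g = int(np.argmin(pbest_f))
            if pbest_f[g] < gbest_f:
                gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
        history.append(gbest_f)

    return PSOResult(gbest, gbest_f, np.asarray(history))


# ---------------------------------------------------------------------------
# Hybrid training
# ---------------------------------------------------------------------------

@dataclass
class TrainingTrace:
    pso_best_fitness: np.ndarray      # per PSO generation
    train_rmse: np.ndarray            # per gradient-descent epoch
    test_rmse: Optional[np.ndarray]   # per epoch, if a test set was given
    final_params: FWNNetParameters


def default_parameter_bounds(X, t, config: NetworkConfig,
                             overrides: Optional[dict] = None):
    """Data-driven search box per parameter group.

    Centers and translations span the observed feature range, widths span
    (sigma floor, range], dilations (dilation floor, range], and consequent
    weights/biases a symmetric interval wide enough to reach the target
    range.  ``overrides`` maps group name -> (lo, hi) scalars.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float)
    xlo, xhi = X.min(axis=0), X.max(axis=0)
    span = np.where(xhi > xlo, xhi - xlo, 1.0)
    wy = max(2.0, float(np.max(np.abs(t))) if t.size else 2.0)
    per_group = {
        "c": (xlo, xhi),
        "sigma": (np.full_like(span, SIGMA_MIN), span),
        "b": (xlo, xhi),
        "a": (np.full_like(span, A_MIN), span),
        "w": (-wy, wy),
        "ybar": (-wy, wy),
    }
    if overrides:
        for gname, pair in overrides.items():
            per_group[gname] = pair
    shapes = FWNNetParameters.group_shapes(config)
    lo_parts, hi_parts = [], []
    for gname, shape in shapes.items():
        glo, ghi = per_group[gname]
        lo_parts.append(np.broadcast_to(np.asarray(glo, float), shape).ravel())
        hi_parts.append(np.broadcast_to(np.asarray(ghi, float), shape).ravel())
    return np.concatenate(lo_parts), np.concatenate(hi_parts)


def _inline_blocks(config: NetworkConfig):
    sl = FWNNetParameters.group_slices(config)
    pairs = (("c", "sigma"), ("b", "a"), ("w", "ybar"))
    return [np.concatenate([np.arange(sl[g1].start, sl[g1].stop),
                            np.arange(sl[g2].start, sl[g2].stop)])
            for g1, g2 in pairs]


def _rescale_params(params: FWNNetParameters, mean: np.ndarray,
                    scale: np.ndarray, config: NetworkConfig
                    ) -> FWNNetParameters:
    """Map parameters trained on x' = (x - mean)/scale back to raw units.

    The network is exactly invariant under this affine reparameterization:
    c, b -> mean + scale * (c, b); sigma, a -> scale * (sigma, a); with the
    |a|^(-1/2) prefactor enabled the product picks up a constant
    prod_j scale_j^(-1/2) which is absorbed into the weights.
    """
    out = params.copy()
    out.c = mean + scale * params.c
    out.sigma = scale * params.sigma
    out.b = mean[None, None, :] + scale[None, None, :] * params.b
    out.a = scale[None, None, :] * params.a
    if config.normalize_wavelet:
        out.w = params.w * float(np.prod(np.sqrt(scale)))
    return out


def hybrid_train(X, t, config: NetworkConfig,
                 train_config: Optional[TrainingConfig] = None,
                 pso_config: Optional[PSOConfig] = None,
                 X_test=None, t_test=None,
                 pso_subsample: Optional[int] = None,
                 standardize: bool = True):
    """PSO initialization followed by gradient descent on the full dataset.

    Parameters
    ----------
    X, t : arrays of shape (B, n) and (B,)
        Training features and numeric targets (class labels are used
        directly as regression targets in classification mode).
    X_test, t_test : optional held-out set traced per epoch.
    pso_subsample : optional cap on the number of samples used inside the
        PSO objective (seeded subsample; gradient descent always uses the
        full set).
    standardize : train on z-scored features (default) and map the fitted
        parameters back to raw feature units on return, so per-group
        learning rates are meaningful regardless of the input scale.

    Returns (final_params, TrainingTrace).
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("dataset must be non-empty with shape (B, n)")
    if X.shape[1] != config.n:
        raise ValueError(f"feature dimension {X.shape[1]} != config.n {config.n}")
    train_config = train_config or TrainingConfig()
    pso_config = pso_config or PSOConfig()

    feat_mean = np.zeros(config.n)
    feat_scale = np.ones(config.n)
    if standardize:
        feat_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        feat_scale = np.where(sd > 0, sd, 1.0)
        X = (X - feat_mean) / feat_scale
        if X_test is not None:
            X_test = (np.asarray(X_test, float) - feat_mean) / feat_scale

    lo, hi = default_parameter_bounds(X, t, config,
                                      pso_config.position_bounds)

    Xo, to = X, t
    if pso_subsample is not None and pso_subsample < X.shape[0]:
        sub_rng = np.random.default_rng(pso_config.rng_seed)
        idx = sub_rng.choice(X.shape[0], pso_subsample, replace=False)
        Xo, to = X[idx], t[idx]

    def objective(vec: np.ndarray) -> float:
        params = FWNNetParameters.from_vector(vec, config)
        params.sigma = np.maximum(params.sigma, SIGMA_MIN)
        y = batch_forward(Xo, params, config, strict=False)
        if not np.all(np.isfinite(y)):
            return np.inf
        return float(np.sqrt(np.mean((y - to) ** 2)))

    blocks = _inline_blocks(config) if pso_config.mode == "inline_pso" else None
    pso_result = pso_optimize(objective, lo, hi, pso_config, blocks=blocks)

    params = FWNNetParameters.from_vector(pso_result.best_position, config)
    params.sigma = np.maximum(params.sigma, SIGMA_MIN)
    sign = np.where(np.sign(params.a) == 0, 1.0, np.sign(params.a))
    params.a = sign * np.maximum(np.abs(params.a), A_MIN)

    rng = np.random.default_rng(train_config.rng_seed)
    check_acc = train_config.stop_at_full_accuracy and config.num_classes >= 2
    train_curve, test_curve = [], []
    for _ in range(train_config.max_epochs):
        if train_config.batch_mode == "full":
            grads = batch_gradients(X, t, params, config)
            params = gradient_step(params, grads, train_config)
        else:
            order = rng.permutation(X.shape[0])
            for i in order:
                grads = batch_gradients(X[i:i + 1], t[i:i + 1], params, config)
                params = gradient_step(params, grads, train_config)
        y_hat = batch_forward(X, params, config)
        tr = float(np.sqrt(np.mean((y_hat - t) ** 2)))
        train_curve.append(tr)
        if X_test is not None:
            test_curve.append(rmse(X_test, t_test, params, config))
        if tr <= train_config.loss_floor:
            break
        if check_acc:
            from .model import classify
            if np.all(classify(y_hat, config.num_classes) == t.astype(int)):
                break

    if standardize:
        params = _rescale_params(params, feat_mean, feat_scale, config)

    trace = TrainingTrace(
        pso_best_fitness=pso_result.history,
        train_rmse=np.asarray(train_curve),
        test_rmse=np.asarray(test_curve) if X_test is not None else None,
        final_params=params,
    )
    return params, trace


def train_classifier(X, labels, num_classes: int,
                     M: int = 2, N_k: int = 4, seed: int = 0,
                     learning_rate: float = 0.05, max_epochs: int = 4000,
                     max_restarts: int = 3,
                     pso_config: Optional[PSOConfig] = None):
    """Hybrid-train an FWNNet classifier against its numeric labels.

    Labels 0..num_classes-1 are used directly as regression targets and
    training stops as soon as every sample rounds to its own label (or at
    ``max_epochs``).  If perfect training accuracy is not reached the whole
    hybrid run restarts from a deterministically shifted swarm seed, up to
    ``max_restarts`` attempts; the best attempt (accuracy, then RMSE) is
    returned.  Returns (params, config, trace).
    """
    from .model import predict_labels

    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    config = NetworkConfig(n=X.shape[1], M=M, N_k=N_k,
                           num_classes=num_classes)
    best = None
    for attempt in range(max_restarts):
        attempt_seed = seed + 1000 * attempt
        train_config = TrainingConfig(
            gamma_c=learning_rate, gamma_sigma=learning_rate,
            gamma_b=learning_rate, gamma_a=learning_rate,
            gamma_w=learning_rate, gamma_ybar=learning_rate,
            max_epochs=max_epochs, rng_seed=attempt_seed,
            stop_at_full_accuracy=True)
        pcfg = pso_config or PSOConfig(rng_seed=attempt_seed)
        if pso_config is not None:
            pcfg = PSOConfig(**{**pso_config.__dict__,
                                "rng_seed": pso_config.rng_seed
                                + 1000 * attempt})
        params, trace = hybrid_train(X, labels.astype(float), config,
                                     train_config, pcfg)
        acc = float(np.mean(predict_labels(X, params, config) == labels))
        key = (acc, -trace.train_rmse[-1])
        if best is None or key > best[0]:
            best = (key, params, trace)
        if acc == 1.0:
            break
    _, params, trace = best
    return params, config, trace
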