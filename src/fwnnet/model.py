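"""Eight-layer fuzzy wavelet neural network (FWNNet) forward computation.

The network combines a Takagi-Sugeno-Kang fuzzy system with wavelet-network
rule consequents:

    layer 1   inputs x_1..x_n
    layer 2   per-feature wavelet activations psi_ijk and Gaussian fuzzy
              memberships mu_kj
    layer 3   per-rule products: wavelet products Psi_ik and firing
              strengths O_k (product AND)
    layer 4   rule consequents Y_k = sum_i w_ik Psi_ik + ybar_k
    layer 5   O_k * Y_k
    layer 6   the two sums  O6_1 = sum_k O_k Y_k  and  O6_2 = sum_k O_k
    layer 7   defuzzified output y = O6_1 / O6_2
    layer 8   (classification only) round to the nearest label, clamped

Array convention: everything is rule-major.  With M rules, N wavelet neurons
per rule and n features the parameter shapes are c, sigma: (M, n);
b, a: (M, N, n); w: (M, N); ybar: (M,).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from .config import A_MIN, EPS_DEN, SIGMA_MIN, ConfigurationError, NetworkConfig

MORLET_OMEGA0 = 5.0  # carrier frequency of the real-valued Morlet wavelet


class DegenerateInputError(ValueError):
    """No rule fires: the defuzzification denominator is below its floor."""


class InvalidWidthError(ValueError):
    """A membership width sigma is not strictly positive."""


class DilationFloorError(ValueError):
    """A wavelet dilation |a| is below the configured floor."""


# ---------------------------------------------------------------------------
# Mother wavelets
# ---------------------------------------------------------------------------

def mother_wavelet(x, family: str = "mexican_hat"):
    """Evaluate the mother wavelet psi(x).

    mexican_hat: psi(x) = (1 - x^2) exp(-x^2 / 2)
    morlet:      psi(x) = cos(omega0 x) exp(-x^2 / 2), omega0 = 5
    """
    x = np.asarray(x, dtype=float)
    if family == "mexican_hat":
        return (1.0 - x * x) * np.exp(-0.5 * x * x)
    if family == "morlet":
        return np.cos(MORLET_OMEGA0 * x) * np.exp(-0.5 * x * x)
    raise ConfigurationError(f"unknown wavelet family {family!r}")


def mother_wavelet_derivative(x, family: str = "mexican_hat"):
    """d psi / dx, used by the analytic gradients."""
    x = np.asarray(x, dtype=float)
    if family == "mexican_hat":
        # d/dx [(1-x^2) e^{-x^2/2}] = x (x^2 - 3) e^{-x^2/2}
        return x * (x * x - 3.0) * np.exp(-0.5 * x * x)
    if family == "morlet":
        w0 = MORLET_OMEGA0
        return (-w0 * np.sin(w0 * x) - x * np.cos(w0 * x)) * np.exp(-0.5 * x * x)
    raise ConfigurationError(f"unknown wavelet family {family!r}")


def check_admissibility(family: Union[str, Callable[[np.ndarray], np.ndarray]],
                        ) -> bool:
    """Numerically test the wavelet admissibility condition.

    C_psi = int_0^inf |psi_hat(omega)| / omega d omega must be finite, which
    requires psi_hat(0) = int psi dx = 0.  The Fourier transform is estimated
    by quadrature on a wide grid and the integrand's omega -> 0 limit is
    inspected: a non-vanishing |psi_hat(0)| makes the integral logarithmically
    divergent.

    ``family`` may be a family name or any callable psi(x) (used in tests).
    """
    if callable(family):
        psi = family
    else:
        fam = family
        psi = lambda x: mother_wavelet(x, fam)  # noqa: E731
    x = np.linspace(-40.0, 40.0, 2 ** 13)
    fx = np.asarray(psi(x), dtype=float)
    abs_mass = np.trapezoid(np.abs(fx), x)
    if abs_mass == 0.0:
        return False
    omega = np.logspace(-3, 1.7, 400)
    # psi_hat(omega) = int psi(x) e^{-i omega x} dx by trapezoid quadrature
    kernel = np.exp(-1j * np.outer(omega, x))
    psi_hat = np.trapezoid(kernel * fx, x, axis=1)
    # omega->0 limit of |psi_hat|: nonzero mean => divergent C_psi
    return bool(np.abs(psi_hat[0]) < 1e-4 * abs_mass)


def admissibility_constant(family: str) -> float:
    """Grid estimate of C_psi (informational; finite for shipped families)."""
    x = np.linspace(-40.0, 40.0, 2 ** 13)
    fx = mother_wavelet(x, family)
    omega = np.logspace(-3, 1.7, 400)
    kernel = np.exp(-1j * np.outer(omega, x))
    psi_hat = np.abs(np.trapezoid(kernel * fx, x, axis=1))
    return float(np.trapezoid(psi_hat / omega, omega))


# ---------------------------------------------------------------------------
# Elementary layer operations (scalar contracts; all accept arrays)
# ---------------------------------------------------------------------------

def wavelet_activation(x_j, b, a, config: NetworkConfig):
    """Dilated/translated wavelet psi((x - b)/a), optionally |a|^(-1/2)-scaled."""
    a = np.asarray(a, dtype=float)
    if np.any(np.abs(a) < A_MIN):
        raise DilationFloorError(f"|a| must be >= {A_MIN}")
    z = (np.asarray(x_j, dtype=float) - b) / a
    out = mother_wavelet(z, config.wavelet_family)
    if config.normalize_wavelet:
        out = out / np.sqrt(np.abs(a))
    return out


def membership(x_j, c, sigma):
    """Gaussian fuzzy membership mu = exp(-((x - c)/sigma)^2).

    Note the exponent carries no 1/2 factor.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise InvalidWidthError("sigma must be > 0")
    u = (np.asarray(x_j, dtype=float) - c) / sigma
    return np.exp(-u * u)


def rule_wavelet_product(psi_values):
    """Psi_ik = product over features j of psi_ijk (last axis)."""
    return np.prod(np.asarray(psi_values, dtype=float), axis=-1)


def firing_strength(mu_values):
    """O_k = product over features j of mu_kj (product t-norm, last axis)."""
    return np.prod(np.asarray(mu_values, dtype=float), axis=-1)


def rule_output(x, k: int, params: "FWNNetParameters", config: NetworkConfig):
    """Consequent of rule k: Y_k = sum_i w_ik Psi_ik + ybar_k."""
    x = np.asarray(x, dtype=float)
    psi = wavelet_activation(x[None, :], params.b[k], params.a[k], config)
    Psi = rule_wavelet_product(psi)
    return float(params.w[k] @ Psi + params.ybar[k])


def defuzzify(O, Y):
    """Firing-strength-weighted mean y = sum_k O_k Y_k / sum_k O_k."""
    O = np.asarray(O, dtype=float)
    Y = np.asarray(Y, dtype=float)
    den = O.sum(axis=-1)
    if np.any(den <= EPS_DEN):
        raise DegenerateInputError(
            "all rules inactive: firing-strength sum below floor")
    return (O * Y).sum(axis=-1) / den


def classify(y, num_classes: int):
    """Eighth layer: round half away from zero, then clamp to the label range."""
    if num_classes < 2:
        raise ConfigurationError("classification needs num_classes >= 2")
    y = np.asarray(y, dtype=float)
    rounded = np.copysign(np.floor(np.abs(y) + 0.5), y)
    clamped = np.clip(rounded, 0, num_classes - 1)
    if clamped.ndim == 0:
        return int(clamped)
    return clamped.astype(int)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class FWNNetParameters:
    """Trainable parameter set Theta = {c, sigma, b, a, w, ybar}."""

    c: np.ndarray       # (M, n) membership centers
    sigma: np.ndarray   # (M, n) membership widths, > 0
    b: np.ndarray       # (M, N, n) wavelet translations
    a: np.ndarray       # (M, N, n) wavelet dilations, |a| >= A_MIN
    w: np.ndarray       # (M, N) consequent weights
    ybar: np.ndarray    # (M,) consequent biases

    def validate(self, config: NetworkConfig) -> None:
        M, N, n = config.M, config.N_k, config.n
        shapes = {
            "c": (self.c, (M, n)), "sigma": (self.sigma, (M, n)),
            "b": (self.b, (M, N, n)), "a": (self.a, (M, N, n)),
            "w": (self.w, (M, N)), "ybar": (self.ybar, (M,)),
        }
        for name, (arr, want) in shapes.items():
            if arr.shape != want:
                raise ValueError(f"{name} has shape {arr.shape}, want {want}")
        if np.any(self.sigma <= 0):
            raise InvalidWidthError("all sigma must be > 0")
        if np.any(np.abs(self.a) < A_MIN):
            raise DilationFloorError(f"all |a| must be >= {A_MIN}")

    def copy(self) -> "FWNNetParameters":
        return FWNNetParameters(*(getattr(self, f).copy()
                                  for f in ("c", "sigma", "b", "a", "w", "ybar")))

    # -- flat-vector codec (used by PSO and serialization) ------------------
    GROUPS = ("c", "sigma", "b", "a", "w", "ybar")

    @staticmethod
    def group_shapes(config: NetworkConfig) -> dict:
        M, N, n = config.M, config.N_k, config.n
        return {"c": (M, n), "sigma": (M, n), "b": (M, N, n),
                "a": (M, N, n), "w": (M, N), "ybar": (M,)}

    @staticmethod
    def group_slices(config: NetworkConfig) -> dict:
        out, start = {}, 0
        for g, shp in FWNNetParameters.group_shapes(config).items():
            size = int(np.prod(shp))
            out[g] = slice(start, start + size)
            start += size
        return out

    def to_vector(self) -> np.ndarray:
        return np.concatenate([getattr(self, g).ravel() for g in self.GROUPS])

    @classmethod
    def from_vector(cls, vec: np.ndarray, config: NetworkConfig
                    ) -> "FWNNetParameters":
        vec = np.asarray(vec, dtype=float)
        shapes = cls.group_shapes(config)
        slices = cls.group_slices(config)
        return cls(**{g: vec[slices[g]].reshape(shapes[g]).copy()
                      for g in cls.GROUPS})

    @classmethod
    def random(cls, config: NetworkConfig, rng: np.random.Generator,
               feature_low=0.0, feature_high=1.0, wy_bound: float = 2.0
               ) -> "FWNNetParameters":
        """Draw parameters uniformly inside the default search box."""
        M, N, n = config.M, config.N_k, config.n
        lo = np.broadcast_to(np.asarray(feature_low, float), (n,))
        hi = np.broadcast_to(np.asarray(feature_high, float), (n,))
        span = np.maximum(hi - lo, 1.0)
        return cls(
            c=rng.uniform(lo, hi, (M, n)),
            sigma=rng.uniform(0.1 * span, span, (M, n)),
            b=rng.uniform(lo, hi, (M, N, n)),
            a=rng.uniform(0.1 * span, span, (M, N, n)),
            w=rng.uniform(-wy_bound, wy_bound, (M, N)),
            ybar=rng.uniform(-wy_bound, wy_bound, M),
        )

    # -- JSON persistence ---------------------------------------------------
    def to_json(self, config: NetworkConfig) -> str:
        doc = {
            "config": {
                "n": config.n, "M": config.M, "N_k": config.N_k,
                "num_classes": config.num_classes,
                "wavelet_family": config.wavelet_family,
                "normalize_wavelet": config.normalize_wavelet,
            },
            "parameters": {g: getattr(self, g).tolist() for g in self.GROUPS},
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str):
        doc = json.loads(text)
        config = NetworkConfig(**doc["config"])
        params = cls(**{g: np.asarray(doc["parameters"][g], dtype=float)
                        for g in cls.GROUPS})
        params.validate(config)
        return params, config


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

@dataclass
class ForwardTrace:
    """All intermediate layer outputs for one input vector."""

    mu: np.ndarray     # (M, n)
    psi: np.ndarray    # (M, N, n)
    Psi: np.ndarray    # (M, N)
    O: np.ndarray      # (M,)
    Y: np.ndarray      # (M,)
    O5: np.ndarray     # (M,) = O * Y
    O6_1: float
    O6_2: float
    y: float


def _batch_layers(X: np.ndarray, params: FWNNetParameters,
                  config: NetworkConfig):
    """Vectorized layers 1-7 for X of shape (B, n).

    Returns (z, psi, Psi, u, mu, O, Y, den, y); ``den`` may violate the
    denominator floor — callers decide whether that is an error.
    """
    z = (X[:, None, None, :] - params.b[None]) / params.a[None]   # (B,M,N,n)
    psi = mother_wavelet(z, config.wavelet_family)
    if config.normalize_wavelet:
        psi = psi / np.sqrt(np.abs(params.a))[None]
    Psi = psi.prod(axis=-1)                                       # (B,M,N)
    u = (X[:, None, :] - params.c[None]) / params.sigma[None]     # (B,M,n)
    mu = np.exp(-u * u)
    O = mu.prod(axis=-1)                                          # (B,M)
    Y = (params.w[None] * Psi).sum(axis=-1) + params.ybar[None]   # (B,M)
    den = O.sum(axis=-1)                                          # (B,)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = (O * Y).sum(axis=-1) / den
    return z, psi, Psi, u, mu, O, Y, den, y


def batch_forward(X: np.ndarray, params: FWNNetParameters,
                  config: NetworkConfig, *, strict: bool = True) -> np.ndarray:
    """Network output y for a batch of inputs X of shape (B, n).

    With ``strict`` (default) a firing-strength sum at or below the
    denominator floor raises :class:`DegenerateInputError`; otherwise the
    affected outputs are NaN.
    """
    X = np.asarray(X, dtype=float)
    *_, den, y = _batch_layers(X, params, config)
    if strict and np.any(den <= EPS_DEN):
        raise DegenerateInputError(
            "all rules inactive for at least one input")
    if not strict:
        y = np.where(den <= EPS_DEN, np.nan, y)
    return y


def forward(x, params: FWNNetParameters, config: NetworkConfig) -> ForwardTrace:
    """Full forward pass for a single feature vector, keeping every layer."""
    x = np.asarray(x, dtype=float)
    if x.shape != (config.n,):
        raise ValueError(f"x has shape {x.shape}, want ({config.n},)")
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    params.validate(config)
    _, psi, Psi, _, mu, O, Y, den, y = _batch_layers(x[None], params, config)
    if den[0] <= EPS_DEN:
        raise DegenerateInputError("all rules inactive for this input")
    O5 = O[0] * Y[0]
    return ForwardTrace(mu=mu[0], psi=psi[0], Psi=Psi[0], O=O[0], Y=Y[0],
                        O5=O5, O6_1=float(O5.sum()), O6_2=float(den[0]),
                        y=float(y[0]))


def predict_labels(X, params: FWNNetParameters, config: NetworkConfig):
    """Convenience: batch forward + eighth-layer rounding."""
    y = batch_forward(np.asarray(X, dtype=float), params, config)
    return classify(y, config.num_classes)
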