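"""Histogram-based feature extraction for 8-bit grayscale images.

Each image's normalized 256-bin intensity histogram is modeled as a sum of
four Gaussian modes

    h(v) ~ sum_{g=1..4} A_g exp(-((v - m_g) / s_g)^2)

fitted by multi-start nonlinear least squares; the fitted mode parameters
(by default the four sorted means) are the per-image features fed to the
classifier.  An eigenface-style covariance reduction over vectorized images
is available as an independent, composable step.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

N_MODES = 4


class FitFailureError(RuntimeError):
    """All least-squares starts diverged; carries the best residual seen."""

    def __init__(self, message: str, best_residual: float = np.inf):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass
class HistogramModel:
    """Fitted four-Gaussian description of one image histogram.

    Means are stored sorted ascending (canonical order); ``residual_norm``
    is the L2 norm of the fit residual over the 256 bin centers.
    """

    amplitudes: np.ndarray   # (4,) >= 0
    means: np.ndarray        # (4,) in [0, 255], ascending
    widths: np.ndarray       # (4,) > 0
    residual_norm: float
    bin_edges: np.ndarray = field(
        default_factory=lambda: np.arange(257, dtype=float))

    def evaluate(self, v) -> np.ndarray:
        """Model density at intensities v."""
        v = np.asarray(v, dtype=float)[..., None]
        return np.sum(self.amplitudes
                      * np.exp(-((v - self.means) / self.widths) ** 2),
                      axis=-1)


def image_histogram(image) -> np.ndarray:
    """Normalized 256-bin histogram of an 8-bit grayscale image."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    values = image.ravel()
    if values.min() < 0 or values.max() > 255:
        raise ValueError("pixel values must lie in [0, 255]")
    counts = np.bincount(values.astype(np.int64), minlength=256)[:256]
    return counts / counts.sum()


def _pack(A, m, s):
    return np.concatenate([A, m, s])


def _unpack(theta):
    return theta[:N_MODES], theta[N_MODES:2 * N_MODES], theta[2 * N_MODES:]


def _residuals(theta, v, hist):
    A, m, s = _unpack(theta)
    model = np.sum(A * np.exp(-((v[:, None] - m) / s) ** 2), axis=1)
    return model - hist


def _weighted_quantiles(hist, v, qs):
    cdf = np.cumsum(hist)
    cdf = cdf / cdf[-1]
    return np.interp(qs, cdf, v)


def fit_four_gaussians(hist, seed: int = 0, n_starts: int = 5
                       ) -> HistogramModel:
    """Fit the sum-of-four-Gaussians model to a normalized histogram.

    Multi-start bounded least squares: the first start places the means at
    the quartile-spaced weighted quantiles of the histogram, the remaining
    seeded starts jitter means and widths.  The lowest-residual solution is
    returned with modes sorted by mean.
    """
    hist = np.asarray(hist, dtype=float)
    if hist.shape != (256,):
        raise ValueError("expected a 256-bin histogram")
    if not np.isclose(hist.sum(), 1.0, atol=1e-6):
        raise ValueError("histogram must be normalized to sum 1")
    v = np.arange(256, dtype=float) + 0.5  # bin centers
    rng = np.random.default_rng(seed)

    peak = max(hist.max(), 1e-12)
    lb = _pack(np.zeros(N_MODES), np.zeros(N_MODES), np.ones(N_MODES))
    ub = _pack(np.full(N_MODES, 2 * peak), np.full(N_MODES, 255.0),
               np.full(N_MODES, 128.0))

    m0 = _weighted_quantiles(hist, v, [0.125, 0.375, 0.625, 0.875])
    starts = [_pack(np.interp(m0, v, hist), m0, np.full(N_MODES, 20.0))]
    for _ in range(n_starts - 1):
        m_j = np.clip(m0 + rng.normal(0, 15, N_MODES), 0, 255)
        s_j = rng.uniform(5, 40, N_MODES)
        A_j = np.clip(np.interp(m_j, v, hist) * rng.uniform(0.5, 1.5, N_MODES),
                      0, 2 * peak)
        starts.append(_pack(A_j, np.sort(m_j), s_j))

    best, best_cost = None, np.inf
    for x0 in starts:
        try:
            sol = least_squares(_residuals, np.clip(x0, lb, ub),
                                bounds=(lb, ub), args=(v, hist),
                                method="trf", max_nfev=2000)
        except Exception:
            continue
        if sol.cost < best_cost and np.all(np.isfinite(sol.x)):
            best, best_cost = sol, sol.cost
    if best is None:
        raise FitFailureError("all least-squares starts diverged",
                              best_residual=best_cost)

    A, m, s = _unpack(best.x)
    order = np.argsort(m)
    resid = _residuals(best.x, v, hist)
    return HistogramModel(amplitudes=A[order], means=m[order],
                          widths=s[order],
                          residual_norm=float(np.linalg.norm(resid)))


def extract_features(model: HistogramModel, mode: str = "means") -> np.ndarray:
    """Per-image feature vector from a fitted histogram model.

    ``means`` (default): the 4 sorted mode means; ``amplitudes``: the 4
    amplitudes; ``all12``: concatenated (A, m, s).
    """
    if mode == "means":
        return model.means.copy()
    if mode == "amplitudes":
        return model.amplitudes.copy()
    if mode == "all12":
        return np.concatenate([model.amplitudes, model.means, model.widths])
    raise ValueError(f"unknown feature mode {mode!r}")


def extract_image_features(image, seed: int = 0, mode: str = "means"
                           ) -> np.ndarray:
    """histogram -> four-Gaussian fit -> feature vector, in one call."""
    return extract_features(fit_four_gaussians(image_histogram(image), seed),
                            mode)


# ---------------------------------------------------------------------------
# Eigenface-style covariance reduction
# ---------------------------------------------------------------------------

@dataclass
class EigenReduction:
    mean_image: np.ndarray    # (P,) mean of the vectorized images
    eigenvalues: np.ndarray   # (K,) descending, real
    eigenvectors: np.ndarray  # (P, retained_count), orthonormal columns
    retained_count: int


def eigen_reduce(images: Sequence[np.ndarray], tol: float = 1e-10
                 ) -> EigenReduction:
    """Principal directions of a stack of vectorized images.

    Images are centered on their mean and the covariance eigenproblem is
    solved in the K x K inner-product (Gram) space, K = number of images —
    the standard eigenface trick — then mapped back to pixel space.
    Eigenvalues are those of the pixel-space covariance C = X_c^T X_c/(K-1).
    """
    X = np.stack([np.asarray(im, dtype=float).ravel() for im in images])
    K = X.shape[0]
    if K < 2:
        raise ValueError("need at least 2 images")
    mean = X.mean(axis=0)
    Xc = X - mean
    gram = Xc @ Xc.T / (K - 1)
    lam, U = np.linalg.eigh(gram)
    order = np.argsort(lam)[::-1]
    lam, U = lam[order], U[:, order]
    keep = lam > tol * max(lam.max(), 1.0)
    retained = int(keep.sum())
    vecs = Xc.T @ U[:, keep]
    if retained:
        vecs /= np.sqrt(lam[keep] * (K - 1))
    return EigenReduction(mean_image=mean,
                          eigenvalues=np.maximum(lam, 0.0),
                          eigenvectors=vecs,
                          retained_count=retained)
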