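"""Synthetic MRI-like phantoms and class-structured datasets.

Phantom background tissue is drawn per pixel from a four-mode Gaussian
intensity mixture (so the image histogram is a sum of four Gaussians, the
model the feature extractor fits); an optional elliptical "tumor" of smooth
intensity is stamped in with a matching binary ground-truth mask (255 inside
the tumor).  Class identity shifts the mixture-mode means by a fixed offset
per class, which is what makes histogram features discriminative.

Defaults: 256 x 256 images, base mode means (40, 100, 160, 220), mode
widths 12 (in the no-half-factor Gaussian convention used by the fitter),
mixture weights (0.35, 0.30, 0.20, 0.15), +10 intensity units of mean shift
per class label.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

# (weight, mean, width) per mode; width s in the exp(-((v-m)/s)^2) convention,
# i.e. the per-pixel sampling standard deviation is s / sqrt(2).
BASE_WEIGHTS = np.array([0.35, 0.30, 0.20, 0.15])
BASE_MEANS = np.array([40.0, 100.0, 160.0, 220.0])
BASE_WIDTHS = np.array([12.0, 12.0, 12.0, 12.0])
CLASS_MEAN_SHIFT = 10.0  # intensity units per class label

CLASS_NAMES = ("Normal", "Glioma", "Meningioma", "Pituitary")


@dataclass
class Ellipse:
    center: Tuple[float, float]  # (row, col)
    axes: Tuple[float, float]    # semi-axes (row, col) in pixels
    angle: float = 0.0           # radians, counterclockwise
    intensity: float = 200.0


@dataclass
class PhantomSpec:
    image_side: int = 256
    class_id: int = 0
    histogram_modes: Optional[np.ndarray] = None  # (4, 3) rows of (A, m, s)
    tumor: Optional[Ellipse] = None
    noise_sd: float = 6.0
    rng_seed: int = 0

    def modes(self) -> np.ndarray:
        if self.histogram_modes is not None:
            modes = np.asarray(self.histogram_modes, dtype=float)
        else:
            modes = np.column_stack([
                BASE_WEIGHTS,
                BASE_MEANS + CLASS_MEAN_SHIFT * self.class_id,
                BASE_WIDTHS,
            ])
        if np.any(modes[:, 1] < 0) or np.any(modes[:, 1] > 255):
            raise ValueError("mode means must lie in [0, 255]")
        return modes


def _ellipse_mask(side: int, ellipse: Ellipse) -> np.ndarray:
    r0, c0 = ellipse.center
    ar, ac = ellipse.axes
    if ar <= 0 or ac <= 0:
        raise ValueError("ellipse semi-axes must be positive")
    if not (0 <= r0 <= side - 1 and 0 <= c0 <= side - 1):
        raise ValueError("tumor center must lie inside the image")
    rr, cc = np.mgrid[0:side, 0:side]
    dr, dc = rr - r0, cc - c0
    ca, sa = np.cos(ellipse.angle), np.sin(ellipse.angle)
    xr = ca * dr + sa * dc
    xc = -sa * dr + ca * dc
    return (xr / ar) ** 2 + (xc / ac) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    """One phantom image and its ground-truth mask (uint8; mask in {0, 255})."""
    if spec.image_side < 1:
        raise ValueError("image_side must be >= 1")
    rng = np.random.default_rng(spec.rng_seed)
    modes = spec.modes()
    weights = modes[:, 0] / modes[:, 0].sum()
    side = spec.image_side

    which = rng.choice(4, size=(side, side), p=weights)
    image = rng.normal(modes[which, 1], modes[which, 2] / np.sqrt(2.0))

    mask = np.zeros((side, side), dtype=np.uint8)
    if spec.tumor is not None:
        inside = _ellipse_mask(side, spec.tumor)
        image[inside] = (spec.tumor.intensity
                         + rng.normal(0.0, spec.noise_sd, int(inside.sum())))
        mask[inside] = 255
    return np.clip(np.round(image), 0, 255).astype(np.uint8), mask


def generate_class_dataset(n_per_class: int, seed: int = 0,
                           mode: str = "features",
                           separation: float = CLASS_MEAN_SHIFT,
                           feature_noise_sd: float = 2.0,
                           image_side: int = 256):
    """Balanced 4-class dataset.

    ``mode="features"`` emits the four histogram-mode means directly, as the
    feature extractor would recover them: class c contributes
    base_means + separation * c + N(0, feature_noise_sd) per sample.
    ``separation=0`` makes the features independent of the labels (a
    chance-level sanity set).  ``mode="images"`` renders full phantoms
    (classes 1-3 carry a tumor, class 0 does not).

    Returns (X, y) with X of shape (4 * n_per_class, 4) in feature mode, or
    (images, y) with a list of uint8 images otherwise.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(4), n_per_class)
    if mode == "features":
        X = (BASE_MEANS[None, :] + separation * labels[:, None]
             + rng.normal(0.0, feature_noise_sd, (labels.size, 4)))
        return X, labels
    if mode == "images":
        images = []
        for lab in labels:
            tumor = None
            if lab > 0:
                tumor = _random_tumor(image_side, rng)
            spec = PhantomSpec(image_side=image_side, class_id=int(lab),
                               tumor=tumor,
                               rng_seed=int(rng.integers(2 ** 31)))
            img, _ = generate_phantom(spec)
            images.append(img)
        return images, labels
    raise ValueError(f"unknown mode {mode!r}")


def _random_tumor(side: int, rng: np.random.Generator,
                  axis_range: Tuple[float, float] = (0.08, 0.20)) -> Ellipse:
    ar = rng.uniform(*axis_range) * side
    ac = rng.uniform(*axis_range) * side
    bound = max(ar, ac) + 1
    r0 = rng.uniform(bound, side - 1 - bound)
    c0 = rng.uniform(bound, side - 1 - bound)
    return Ellipse(center=(r0, c0), axes=(ar, ac),
                   angle=rng.uniform(0, np.pi),
                   intensity=rng.uniform(180.0, 215.0))


def generate_segmentation_set(n_images: int, seed: int = 0,
                              image_side: int = 256,
                              noise_sd: float = 6.0
                              ) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Paired (image, mask) phantoms with randomized tumor geometry.

    Tumor semi-axes are 8-20% of the image side, so the tumor area fraction
    stays within about [0.01, 0.15] of the image.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_images):
        tumor = _random_tumor(image_side, rng)
        spec = PhantomSpec(image_side=image_side,
                           class_id=int(rng.integers(0, 4)),
                           tumor=tumor, noise_sd=noise_sd,
                           rng_seed=int(rng.integers(2 ** 31)))
        out.append(generate_phantom(spec))
    return out
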