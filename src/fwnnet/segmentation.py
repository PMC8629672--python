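"""Patch-based supervised tumor segmentation with an FWNNet regressor.

Pipeline: the grayscale image is texture-transformed by an oriented Gabor
filter bank (smooth tumor tissue responds weakly, the textured background
strongly), then swept into patches — each m x m ground-truth mask patch is
paired with the co-centered 2m x 2m input window.  An FWNNet in regression
mode is trained on (input window, mask pixel) pairs with the hybrid
PSO + gradient-descent scheme, and at inference the per-patch predictions
are averaged back into a full-resolution tumor score map and thresholded.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.filters import gabor

from .config import GaborBank, NetworkConfig, PatchScheme, PSOConfig, TrainingConfig
from .evaluation import UndefinedMetricError, roc_points
from .model import FWNNetParameters, batch_forward
from .training import TrainingTrace, hybrid_train

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Gabor transform
# ---------------------------------------------------------------------------

def _bandwidth_sigma(wavelength: float, bandwidth: float) -> float:
    # standard octave-bandwidth to envelope-sigma relation
    factor = np.sqrt(np.log(2) / 2.0) / np.pi
    return (wavelength * factor * (2.0 ** bandwidth + 1)
            / (2.0 ** bandwidth - 1))


def gabor_transform(image, bank: GaborBank) -> np.ndarray:
    """Per-orientation Gabor magnitude responses, aggregated and rescaled.

    Returns a float array in [0, 1]; shape (H, W) for ``max``/``mean``
    aggregation, (H, W, n_orientations) for ``concat``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if image.size and image.max() > 1.0:
        image = image / 255.0
    sigma_x = _bandwidth_sigma(bank.wavelength, bank.bandwidth)
    sigma_y = sigma_x / bank.aspect
    responses = []
    for theta_deg in bank.orientations:
        real, imag = gabor(image, frequency=1.0 / bank.wavelength,
                           theta=np.deg2rad(theta_deg),
                           sigma_x=sigma_x, sigma_y=sigma_y)
        responses.append(np.hypot(real, imag))
    stack = np.stack(responses, axis=-1)
    if bank.aggregation == "max":
        out = stack.max(axis=-1)
    elif bank.aggregation == "mean":
        out = stack.mean(axis=-1)
    else:  # concat
        out = stack
    lo, hi = out.min(), out.max()
    if hi > lo:
        out = (out - lo) / (hi - lo)
    else:
        out = np.zeros_like(out)
    return out


# ---------------------------------------------------------------------------
# Patch sweep
# ---------------------------------------------------------------------------

def _positions(extent: int, m: int, stride: int) -> np.ndarray:
    pos = list(range(0, extent - m + 1, stride))
    if pos[-1] != extent - m:  # cover the trailing edge
        pos.append(extent - m)
    return np.asarray(pos)


def _pad_input(image: np.ndarray, scheme: PatchScheme) -> np.ndarray:
    before, after = scheme.m // 2, scheme.m - scheme.m // 2
    mode = "reflect" if scheme.padding == "reflect" else "constant"
    return np.pad(image, ((before, after), (before, after)), mode=mode)


def sweep_patches(input_image, mask_image, scheme: PatchScheme):
    """Paired (input window, mask patch) vectors over a sweeping grid.

    For every m x m mask patch position (row-major at the given stride) the
    co-centered 2m x 2m window of the input image is vectorized; the mask
    must contain only {0, 255} and is binarized at 255.

    Returns (X, T, positions): X of shape (P, (2m)^2), T of shape (P, m^2)
    with values in {0.0, 1.0}, and the list of (row, col) patch origins.
    """
    input_image = np.asarray(input_image, dtype=float)
    mask_image = np.asarray(mask_image)
    if input_image.shape != mask_image.shape:
        raise ValueError("input image and mask must have the same shape")
    vals = np.unique(mask_image)
    if not np.all(np.isin(vals, (0, 255))):
        raise ValueError("mask must contain only the values 0 and 255")
    binary = (mask_image == 255).astype(float)

    m, stride = scheme.m, scheme.stride
    H, W = binary.shape
    if H < m or W < m:
        raise ValueError("image smaller than one mask patch")
    rows = _positions(H, m, stride)
    cols = _positions(W, m, stride)

    padded = _pad_input(input_image, scheme)
    in_windows = sliding_window_view(padded, (2 * m, 2 * m))
    mask_windows = sliding_window_view(binary, (m, m))

    X = (in_windows[rows][:, cols]
         .reshape(rows.size * cols.size, 4 * m * m))
    T = (mask_windows[rows][:, cols]
         .reshape(rows.size * cols.size, m * m))
    positions = [(int(r), int(c)) for r in rows for c in cols]
    return X, T, positions


def reassemble_mask(T, positions, shape, scheme: PatchScheme) -> np.ndarray:
    """Average target (or predicted) patch vectors back into an image.

    With stride = m (non-overlapping patches) this inverts
    :func:`sweep_patches` on the mask side exactly.
    """
    m = scheme.m
    acc = np.zeros(shape, dtype=float)
    cnt = np.zeros(shape, dtype=float)
    for vec, (r, c) in zip(np.asarray(T, dtype=float), positions):
        acc[r:r + m, c:c + m] += vec.reshape(m, m)
        cnt[r:r + m, c:c + m] += 1.0
    out = np.zeros(shape, dtype=float)
    np.divide(acc, cnt, out=out, where=cnt > 0)
    return out


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------

@dataclass
class SegmenterModel:
    """Trained patch regressor plus everything needed to apply it."""

    mode: str                       # "shared" | "per_pixel"
    scheme: PatchScheme
    bank: GaborBank
    net_config: NetworkConfig
    params: Optional[FWNNetParameters] = None          # shared mode
    pixel_params: Optional[List[FWNNetParameters]] = None  # per-pixel mode
    trace: Optional[TrainingTrace] = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Continuous tumor scores in [0, 1], shape (P, m^2)."""
        X = np.asarray(X, dtype=float)
        m2 = self.scheme.m ** 2
        out = np.empty((X.shape[0], m2))
        if self.mode == "shared":
            offsets = _pixel_offsets(self.scheme.m)
            for p in range(m2):
                feats = np.hstack([X, np.tile(offsets[p], (X.shape[0], 1))])
                out[:, p] = batch_forward(feats, self.params, self.net_config,
                                          strict=False)
        else:
            for p in range(m2):
                out[:, p] = batch_forward(X, self.pixel_params[p],
                                          self.net_config, strict=False)
        return np.clip(np.nan_to_num(out, nan=0.0), 0.0, 1.0)


def _segmenter_to_doc(model: SegmenterModel) -> dict:
    import dataclasses
    import json

    doc = {
        "mode": model.mode,
        "scheme": dataclasses.asdict(model.scheme),
        "bank": {**dataclasses.asdict(model.bank),
                 "orientations": list(model.bank.orientations)},
        "net_config": dataclasses.asdict(model.net_config),
    }
    if model.mode == "shared":
        doc["params"] = json.loads(model.params.to_json(model.net_config))
    else:
        doc["pixel_params"] = [
            json.loads(p.to_json(model.net_config)) for p in model.pixel_params]
    return doc


def save_segmenter(model: SegmenterModel, path) -> None:
    import json
    from pathlib import Path

    Path(path).write_text(json.dumps(_segmenter_to_doc(model), indent=1))


def load_segmenter(path) -> SegmenterModel:
    import json
    from pathlib import Path

    doc = json.loads(Path(path).read_text())
    scheme = PatchScheme(**doc["scheme"])
    bank = GaborBank(**doc["bank"])
    net_config = NetworkConfig(**doc["net_config"])
    if doc["mode"] == "shared":
        params, _ = FWNNetParameters.from_json(json.dumps(doc["params"]))
        return SegmenterModel(mode="shared", scheme=scheme, bank=bank,
                              net_config=net_config, params=params)
    pixel_params = [FWNNetParameters.from_json(json.dumps(d))[0]
                    for d in doc["pixel_params"]]
    return SegmenterModel(mode="per_pixel", scheme=scheme, bank=bank,
                          net_config=net_config, pixel_params=pixel_params)


def _pixel_offsets(m: int) -> np.ndarray:
    """Normalized (row, col) position of each pixel within an m x m patch."""
    rr, cc = np.divmod(np.arange(m * m), m)
    return np.column_stack([(rr + 0.5) / m, (cc + 0.5) / m])


def train_segmenter(X, T, scheme: PatchScheme,
                    bank: Optional[GaborBank] = None,
                    mode: str = "shared",
                    net_config: Optional[NetworkConfig] = None,
                    train_config: Optional[TrainingConfig] = None,
                    pso_config: Optional[PSOConfig] = None,
                    max_samples: int = 6000,
                    pso_subsample: int = 2000,
                    seed: int = 0) -> SegmenterModel:
    """Train the FWNNet patch regressor on paired (X, T) vectors.

    ``shared`` mode (default) trains a single network whose input is the
    vectorized window plus the normalized (row, col) offset of the target
    pixel; ``per_pixel`` trains one network per mask-patch pixel.  Training
    rows are capped at ``max_samples`` with a seeded subsample.
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty patch dataset")
    bank = bank or GaborBank()
    m2 = scheme.m ** 2
    d = X.shape[1]
    train_config = train_config or TrainingConfig(
        max_epochs=300, rng_seed=seed,
        gamma_c=0.05, gamma_sigma=0.05, gamma_b=0.05,
        gamma_a=0.05, gamma_w=0.05, gamma_ybar=0.05)
    pso_config = pso_config or PSOConfig(rng_seed=seed)
    rng = np.random.default_rng(seed)

    if pso_config.position_bounds is None:
        # With n inputs the product t-norm multiplies n membership values;
        # widths must scale like sqrt(n) (in standardized feature units) or
        # every rule's firing strength underflows.  Same reasoning for the
        # wavelet dilations.
        n_in = d + 2 if mode == "shared" else d
        lo_w = 0.5 * np.sqrt(n_in)
        hi_w = 1.5 * np.sqrt(n_in)
        pso_config = PSOConfig(**{**pso_config.__dict__,
                                  "position_bounds": {"sigma": (lo_w, hi_w),
                                                      "a": (lo_w, hi_w)}})

    if mode == "shared":
        cfg = net_config or NetworkConfig(n=d + 2, num_classes=0)
        offsets = _pixel_offsets(scheme.m)
        rows = np.repeat(np.arange(X.shape[0]), m2)
        offs = np.tile(offsets, (X.shape[0], 1))
        feats = np.hstack([X[rows], offs])
        targets = T.ravel()
        if feats.shape[0] > max_samples:
            idx = rng.choice(feats.shape[0], max_samples, replace=False)
            feats, targets = feats[idx], targets[idx]
        params, trace = hybrid_train(feats, targets, cfg,
                                     train_config, pso_config,
                                     pso_subsample=pso_subsample)
        return SegmenterModel(mode="shared", scheme=scheme, bank=bank,
                              net_config=cfg, params=params, trace=trace)

    if mode == "per_pixel":
        cfg = net_config or NetworkConfig(n=d, num_classes=0)
        pixel_params = []
        for p in range(m2):
            feats, targets = X, T[:, p]
            if feats.shape[0] > max_samples:
                idx = rng.choice(feats.shape[0], max_samples, replace=False)
                feats, targets = feats[idx], targets[idx]
            sub_pso = PSOConfig(**{**pso_config.__dict__,
                                   "rng_seed": pso_config.rng_seed + p})
            params, _ = hybrid_train(feats, targets, cfg,
                                     train_config, sub_pso,
                                     pso_subsample=pso_subsample)
            pixel_params.append(params)
        return SegmenterModel(mode="per_pixel", scheme=scheme, bank=bank,
                              net_config=cfg, pixel_params=pixel_params)

    raise ValueError(f"unknown segmenter mode {mode!r}")


def fit_segmentation(images: Sequence[np.ndarray],
                     masks: Sequence[np.ndarray],
                     scheme: Optional[PatchScheme] = None,
                     bank: Optional[GaborBank] = None,
                     **kwargs) -> SegmenterModel:
    """Gabor-transform a training set, sweep patches, and train."""
    scheme = scheme or PatchScheme()
    bank = bank or GaborBank()
    Xs, Ts = [], []
    for img, msk in zip(images, masks):
        g = gabor_transform(img, bank)
        X, T, _ = sweep_patches(g, msk, scheme)
        Xs.append(X)
        Ts.append(T)
    return train_segmenter(np.vstack(Xs), np.vstack(Ts), scheme, bank=bank,
                           **kwargs)


def segment_image(image, model: SegmenterModel,
                  scheme: Optional[PatchScheme] = None,
                  threshold: float = 0.5
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Score map in [0, 1] and thresholded {0, 255} mask for one image."""
    scheme = scheme or model.scheme
    g = gabor_transform(image, model.bank)
    m, stride = scheme.m, scheme.stride
    H, W = g.shape[:2]
    rows = _positions(H, m, stride)
    cols = _positions(W, m, stride)
    padded = _pad_input(g, scheme)
    windows = sliding_window_view(padded, (2 * m, 2 * m))
    X = windows[rows][:, cols].reshape(rows.size * cols.size, 4 * m * m)
    scores = model.predict(X)
    positions = [(int(r), int(c)) for r in rows for c in cols]
    score_map = reassemble_mask(scores, positions, (H, W), scheme)
    score_map = np.clip(score_map, 0.0, 1.0)
    mask = ((score_map >= threshold) * 255).astype(np.uint8)
    return score_map, mask


def segmentation_roc(score_maps: Sequence[np.ndarray],
                     true_masks: Sequence[np.ndarray]):
    """Pixel-level ROC per image and pooled over all images.

    Images whose mask contains a single class are excluded from the
    per-image list with a logged warning (they still enter the pool).
    Returns (per_image, pooled) where each entry is (fpr, tpr, auc).
    """
    all_scores, all_labels, per_image = [], [], []
    for i, (smap, mask) in enumerate(zip(score_maps, true_masks)):
        smap = np.asarray(smap, dtype=float)
        mask = np.asarray(mask)
        if smap.shape != mask.shape:
            raise ValueError("score map and mask shapes differ")
        labels = (mask > 0).astype(int).ravel()
        scores = smap.ravel()
        all_scores.append(scores)
        all_labels.append(labels)
        try:
            per_image.append(roc_points(scores, labels))
        except UndefinedMetricError:
            logger.warning("image %d has a single-class mask; "
                           "per-image ROC undefined", i)
    pooled = roc_points(np.concatenate(all_scores), np.concatenate(all_labels))
    return per_image, pooled


def dice_coefficient(pred_mask, true_mask) -> float:
    """Dice overlap between two binary masks (any nonzero = positive)."""
    p = np.asarray(pred_mask) > 0
    t = np.asarray(true_mask) > 0
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / denom)
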