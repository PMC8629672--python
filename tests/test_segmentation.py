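"""Tests for the Gabor transform, patch sweep, and segmentation pipeline."""
import numpy as np
import pytest

import fwnnet as fw
from fwnnet import GaborBank, NetworkConfig, PatchScheme, PSOConfig, TrainingConfig
from fwnnet.segmentation import (
    SegmenterModel,
    gabor_transform,
    load_segmenter,
    reassemble_mask,
    save_segmenter,
    segment_image,
    segmentation_roc,
    sweep_patches,
    train_segmenter,
)


def test_gabor_constant_image_near_zero():
    out = gabor_transform(np.full((32, 32), 100, dtype=np.uint8), GaborBank())
    assert out.max() < 1e-6


def test_gabor_grating_orientation_tuning():
    """A vertical grating at the bank wavelength excites the matching
    orientation far more than the orthogonal one."""
    wl = 8.0
    cols = np.arange(64)
    grating = np.tile(np.sin(2 * np.pi * cols / wl), (64, 1))
    bank = GaborBank(orientations=(0.0, 90.0), wavelength=wl,
                     aggregation="concat")
    out = gabor_transform(grating, bank)
    interior = out[16:48, 16:48, :]
    resp = interior.mean(axis=(0, 1))
    assert resp[0] > 5 * resp[1]


def test_gabor_output_range_and_bad_bank():
    rng = np.random.default_rng(0)
    img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
    out = gabor_transform(img, GaborBank())
    assert out.min() >= 0.0 and out.max() <= 1.0
    with pytest.raises(fw.ConfigurationError):
        GaborBank(orientations=())
    with pytest.raises(fw.ConfigurationError):
        GaborBank(wavelength=0.5)


def test_sweep_patch_counts_and_shapes():
    rng = np.random.default_rng(1)
    img = rng.random((8, 8))
    mask = np.zeros((8, 8), dtype=np.uint8)
    mask[2:5, 3:6] = 255
    X, T, pos = sweep_patches(img, mask, PatchScheme(m=2, stride=2))
    assert X.shape == (16, 16)
    assert T.shape == (16, 4)
    assert len(pos) == 16
    assert pos[0] == (0, 0) and pos[-1] == (6, 6)


def test_sweep_zero_mask_and_single_window():
    img = np.random.default_rng(2).random((8, 8))
    zero_mask = np.zeros((8, 8), dtype=np.uint8)
    _, T, _ = sweep_patches(img, zero_mask, PatchScheme(m=2, stride=2))
    assert np.all(T == 0.0)
    X, T, pos = sweep_patches(img, zero_mask, PatchScheme(m=8, stride=8))
    assert X.shape == (1, 256) and T.shape == (1, 64) and pos == [(0, 0)]


def test_sweep_input_window_is_cocentred():
    """With zero padding, the 2m x 2m window around a central mask patch
    contains exactly the corresponding image neighborhood."""
    img = np.arange(64, dtype=float).reshape(8, 8)
    mask = np.zeros((8, 8), dtype=np.uint8)
    X, _, pos = sweep_patches(img, mask, PatchScheme(m=2, stride=2,
                                                     padding="zero"))
    i = pos.index((2, 2))
    window = X[i].reshape(4, 4)
    np.testing.assert_array_equal(window, img[1:5, 1:5])


def test_sweep_errors():
    img = np.zeros((8, 8))
    bad_mask = np.full((8, 8), 7, dtype=np.uint8)
    with pytest.raises(ValueError):
        sweep_patches(img, bad_mask, PatchScheme(m=2))
    with pytest.raises(ValueError):
        sweep_patches(img, np.zeros((6, 6), dtype=np.uint8), PatchScheme(m=2))


@pytest.mark.parametrize("m", [1, 2, 4])
def test_mask_reconstruction_bit_exact(m):
    """Reassembling the target vectors at stride = m reproduces the mask."""
    rng = np.random.default_rng(4)
    side = 16
    img = rng.random((side, side))
    mask = np.where(rng.random((side, side)) > 0.6, 255, 0).astype(np.uint8)
    scheme = PatchScheme(m=m, stride=m)
    _, T, pos = sweep_patches(img, mask, scheme)
    rebuilt = reassemble_mask(T, pos, (side, side), scheme)
    np.testing.assert_array_equal(rebuilt, (mask == 255).astype(float))


def _constant_model(value: float, m: int = 2) -> SegmenterModel:
    """A hand-built segmenter that predicts `value` everywhere."""
    cfg = NetworkConfig(n=4 * m * m + 2, M=1, N_k=1)
    params = fw.FWNNetParameters(
        c=np.zeros((1, cfg.n)), sigma=np.ones((1, cfg.n)) * 100.0,
        b=np.zeros((1, 1, cfg.n)), a=np.ones((1, 1, cfg.n)),
        w=np.zeros((1, 1)), ybar=np.array([value]))
    return SegmenterModel(mode="shared", scheme=PatchScheme(m=m, stride=m),
                          bank=GaborBank(wavelength=4.0), net_config=cfg,
                          params=params)


def test_segment_image_threshold_monotonicity():
    model = _constant_model(0.7)
    img = np.random.default_rng(0).integers(0, 256, (16, 16)).astype(np.uint8)
    smap, mask0 = segment_image(img, model, threshold=0.0)
    np.testing.assert_allclose(smap, 0.7, atol=1e-9)  # uniform score map
    assert np.all(mask0 == 255)
    _, mask1 = segment_image(img, model, threshold=1.01)
    assert np.all(mask1 == 0)


def test_train_segmenter_constant_mapping_and_determinism():
    """Targets that the network can represent exactly (a constant patch
    value) are fit to near-zero RMSE, deterministically in the seed."""
    rng = np.random.default_rng(0)
    X = rng.random((60, 16))
    T = np.full((60, 4), 0.0)
    T[:30] = 1.0
    X[:30] *= 0.05  # low-texture windows are the positive class
    scheme = PatchScheme(m=2, stride=2)
    kw = dict(
        train_config=TrainingConfig(max_epochs=50, rng_seed=0),
        pso_config=PSOConfig(psize=10, maxgen=10, rng_seed=0),
        seed=0)
    m1 = train_segmenter(X, T, scheme, **kw)
    m2 = train_segmenter(X, T, scheme, **kw)
    for g in fw.FWNNetParameters.GROUPS:
        np.testing.assert_array_equal(getattr(m1.params, g),
                                      getattr(m2.params, g))
    scores = m1.predict(X)
    assert scores.shape == (60, 4)
    assert scores.min() >= 0.0 and scores.max() <= 1.0
    rmse = np.sqrt(np.mean((scores - T) ** 2))
    assert rmse < 0.2

    # a single-rule network reproduces a constant mapping exactly
    r = 0.1
    const = train_segmenter(
        X, np.full((60, 4), 0.3), scheme, seed=0,
        net_config=NetworkConfig(n=18, M=1, N_k=1),
        pso_config=PSOConfig(psize=10, maxgen=10, rng_seed=0),
        train_config=TrainingConfig(max_epochs=400, rng_seed=0, gamma_c=r,
                                    gamma_sigma=r, gamma_b=r, gamma_a=r,
                                    gamma_w=r, gamma_ybar=r))
    assert const.trace.train_rmse[-1] < 1e-2


def test_train_segmenter_empty_pairs():
    with pytest.raises(ValueError):
        train_segmenter(np.empty((0, 16)), np.empty((0, 4)),
                        PatchScheme(m=2))


def test_segmenter_json_roundtrip(tmp_path):
    model = _constant_model(0.4)
    path = tmp_path / "seg.json"
    save_segmenter(model, path)
    back = load_segmenter(path)
    assert back.mode == model.mode
    assert back.scheme == model.scheme
    assert back.bank.wavelength == model.bank.wavelength
    img = np.random.default_rng(1).integers(0, 256, (8, 8)).astype(np.uint8)
    s1, _ = segment_image(img, model)
    s2, _ = segment_image(img, back)
    np.testing.assert_array_equal(s1, s2)


def test_segmentation_roc_extremes_and_pooling():
    rng = np.random.default_rng(0)
    mask = np.where(rng.random((40, 40)) > 0.5, 255, 0).astype(np.uint8)
    perfect = (mask / 255.0).astype(float)
    per, pooled = segmentation_roc([perfect], [mask])
    assert per[0][2] == 1.0 and pooled[2] == 1.0

    noise = rng.random((100, 100))
    big_mask = np.where(rng.random((100, 100)) > 0.5, 255, 0).astype(np.uint8)
    _, pooled = segmentation_roc([noise], [big_mask])
    assert abs(pooled[2] - 0.5) < 0.05

    # equal class balance: the pooled AUC lies within the per-image range
    masks = [np.zeros((20, 20), dtype=np.uint8) for _ in range(2)]
    for m in masks:
        m[:10] = 255
    smaps = [m / 255.0 * 0.8 + rng.random((20, 20)) * 0.4 for m in masks]
    per, pooled = segmentation_roc(smaps, masks)
    aucs = [p[2] for p in per]
    assert min(aucs) - 1e-9 <= pooled[2] <= max(aucs) + 1e-9


def test_segmentation_roc_single_class_mask_excluded(caplog):
    rng = np.random.default_rng(1)
    empty = np.zeros((10, 10), dtype=np.uint8)
    full = np.where(rng.random((10, 10)) > 0.5, 255, 0).astype(np.uint8)
    smaps = [rng.random((10, 10)), full / 255.0]
    per, pooled = segmentation_roc(smaps, [empty, full])
    assert len(per) == 1  # the single-class image is skipped per-image
    assert pooled[2] > 0.9


def test_dice_coefficient():
    a = np.zeros((4, 4)); a[:2] = 255
    b = np.zeros((4, 4)); b[:2] = 255
    assert fw.dice_coefficient(a, b) == 1.0
    assert fw.dice_coefficient(a, np.zeros((4, 4))) == 0.0
    assert fw.dice_coefficient(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0
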