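"""Preprocessing operators against independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.signal import convolve2d

from astrodomain import Image, PreprocessParams, generate_scene, preprocess
from astrodomain.imgproc import (
    bandpass,
    binarize_yen,
    despeckle,
    sharpen,
    subtract_background,
)

from conftest import FAST_PP, clean_scene_config


def _img(values, px=0.1, **kw):
    return Image(np.asarray(values, dtype=float), px, **kw)


# ---------------------------------------------------------------- background


def test_background_constant_image_removed():
    out = subtract_background(_img(np.full((64, 64), 137.0)), radius_px=10)
    assert np.all(out.values <= 1.0)


def test_background_all_zero_stays_zero():
    out = subtract_background(_img(np.zeros((32, 32))), radius_px=5)
    assert np.all(out.values == 0.0)


def test_background_spot_on_gradient():
    yy, xx = np.mgrid[0:96, 0:96].astype(float)
    gradient = xx * 2.0
    spot = 500.0 * np.exp(-((xx - 48) ** 2 + (yy - 48) ** 2) / (2 * 2.0**2))
    img = _img(gradient + spot)
    out = subtract_background(img, radius_px=10)
    # spot peak survives within 10%, the gradient residual nearly vanishes
    assert out.values.max() > 0.9 * 500.0
    corner = out.values[:20, :20]
    assert corner.max() < 0.05 * (gradient + spot).max()


def test_background_equals_grey_opening_oracle(rng):
    from skimage.morphology import disk

    values = rng.random((48, 48)) * 100
    out = subtract_background(_img(values), radius_px=6)
    oracle = values - ndi.grey_opening(values, footprint=disk(6))
    np.testing.assert_allclose(out.values, np.clip(oracle, 0, None), atol=1e-9)


def test_background_large_radius_approximates_direct_opening(rng):
    # the downscaled estimate must stay close to the exact opening on
    # smooth content and never overshoot the signal
    yy, xx = np.mgrid[0:128, 0:128].astype(float)
    values = 200 + 100 * np.sin(xx / 40.0) + 50 * np.cos(yy / 25.0)
    from skimage.morphology import disk

    out = subtract_background(_img(values), radius_px=24)
    exact = np.clip(values - ndi.grey_opening(values, footprint=disk(24)), 0, None)
    assert np.all(out.values >= -1e-9)
    assert np.abs(out.values - exact).max() < 0.1 * np.ptp(values)


def test_background_radius_validation():
    img = _img(np.zeros((16, 16)))
    with pytest.raises(ValueError):
        subtract_background(img, radius_px=0)
    with pytest.raises(ValueError):
        subtract_background(img, radius_px=16)


# ------------------------------------------------------------------ bandpass


def test_bandpass_removes_dc():
    out = bandpass(_img(np.full((64, 64), 41.0)), 3, 20)
    assert np.abs(out.values).max() < 1e-6


def test_bandpass_frequency_response():
    # grating with period inside the pass band keeps >= 50% amplitude;
    # period 10x the large cutoff is suppressed to <= 10%
    n = 400
    x = np.arange(n, dtype=float)
    small, large = 4.0, 40.0
    inside = np.sin(2 * np.pi * x / 16.0)  # period 16 px, between 4 and 40
    out_in = bandpass(_img(np.tile(inside, (8, 1))), small, large)
    assert np.ptp(out_in.values[4, n // 4 : -n // 4]) >= 0.5 * 2.0

    slow = np.sin(2 * np.pi * x / 400.0)  # period 10x large cutoff
    out_slow = bandpass(_img(np.tile(slow, (8, 1))), small, large)
    assert np.ptp(out_slow.values[4, n // 4 : -n // 4]) <= 0.1 * 2.0


def test_bandpass_equals_difference_of_gaussians_oracle(rng):
    # independent oracle: explicit sampled-Gaussian kernels + convolve2d
    def gauss_kernel(sigma):
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1, dtype=float)
        phi = np.exp(-0.5 * (x / sigma) ** 2)
        return phi / phi.sum()

    values = rng.random((64, 64)) * 100
    small, large = 3.0, 12.0
    out = bandpass(_img(values), small, large)

    def blur(v, sigma):
        k = gauss_kernel(sigma)
        tmp = convolve2d(v, k[None, :], mode="same", boundary="symm")
        return convolve2d(tmp, k[:, None], mode="same", boundary="symm")

    oracle = blur(values, small / 2.0) - blur(values, large / 2.0)
    np.testing.assert_allclose(out.values, oracle, rtol=1e-6, atol=1e-6)


def test_bandpass_band_validation():
    with pytest.raises(ValueError):
        bandpass(_img(np.zeros((8, 8))), 10, 10)


# ----------------------------------------------------------------- despeckle


def test_despeckle_uniform_unchanged_and_impulse_removed():
    img = _img(np.full((16, 16), 9.0))
    np.testing.assert_array_equal(despeckle(img, 3).values, img.values)

    impulse = np.full((16, 16), 10.0)
    impulse[8, 8] = 1000.0
    out = despeckle(_img(impulse), 3)
    assert out.values[8, 8] == 10.0


def test_despeckle_equals_sorted_median_oracle(rng):
    values = rng.random((32, 32)) * 50
    out = despeckle(_img(values), 3)
    padded = np.pad(values, 1, mode="symmetric")  # scipy 'reflect' repeats edges
    oracle = np.empty_like(values)
    for i in range(32):
        for j in range(32):
            oracle[i, j] = np.sort(padded[i : i + 3, j : j + 3].ravel())[4]
    np.testing.assert_allclose(out.values, oracle)


def test_despeckle_kernel_validation():
    with pytest.raises(ValueError):
        despeckle(_img(np.zeros((8, 8))), 4)


# ------------------------------------------------------------------- sharpen


def test_sharpen_constant_unchanged_with_unit_sum_kernel():
    img = _img(np.full((16, 16), 25.0))
    np.testing.assert_allclose(sharpen(img).values, img.values)


def test_sharpen_boosts_isolated_spot_peak():
    values = np.zeros((21, 21))
    values[10, 10] = 100.0
    values[9:12, 9:12] += 20.0
    out = sharpen(_img(values))
    assert out.values[10, 10] > values[10, 10]


def test_sharpen_equals_nested_loop_convolution_oracle(rng):
    values = rng.random((16, 16)) * 10
    kernel = rng.random((3, 3)) - 0.3
    out = sharpen(_img(values), kernel)
    flipped = kernel[::-1, ::-1]  # convolution flips the kernel
    padded = np.pad(values, 1, mode="symmetric")  # scipy 'reflect' repeats edges
    oracle = np.zeros_like(values)
    for i in range(16):
        for j in range(16):
            oracle[i, j] = (padded[i : i + 3, j : j + 3] * flipped).sum()
    np.testing.assert_allclose(out.values, np.clip(oracle, 0, None), atol=1e-9)


# ----------------------------------------------------------------------- Yen


def _yen_bruteforce_threshold(values: np.ndarray, bins: int) -> float:
    """Exhaustive maximization of the Yen criterion over histogram boundaries."""
    norm = (values - values.min()) / np.ptp(values)
    counts, edges = np.histogram(norm, bins=bins, range=(0, 1))
    centers = (edges[:-1] + edges[1:]) / 2.0
    p = counts / counts.sum()
    best_t, best_crit = 0, -np.inf
    for t in range(len(p) - 1):
        p1 = p[: t + 1].sum()
        g1 = (p[: t + 1] ** 2).sum()
        g2 = (p[t + 1 :] ** 2).sum()
        if g1 <= 0 or g2 <= 0 or p1 <= 0 or p1 >= 1:
            continue
        crit = np.log((p1 * (1 - p1)) ** 2 / (g1 * g2))
        if crit > best_crit:
            best_crit, best_t = crit, t
    return values.min() + centers[best_t] * np.ptp(values)


def test_yen_two_level_image():
    values = np.full((20, 20), 10.0)
    values[5:9, 5:9] = 200.0
    mask, thr = binarize_yen(_img(values))
    assert 10.0 < thr < 200.0
    np.testing.assert_array_equal(mask, values == 200.0)


def test_yen_matches_exhaustive_criterion_search(rng):
    for _ in range(5):
        values = np.concatenate(
            [rng.normal(30, 5, 600), rng.normal(120, 20, 100)]
        ).reshape(20, 35)
        mask, thr = binarize_yen(_img(values), bins=128)
        oracle = _yen_bruteforce_threshold(values, 128)
        assert thr == pytest.approx(oracle, abs=np.ptp(values) / 128)
        np.testing.assert_array_equal(mask, values > thr)


def test_yen_mask_invariant_under_affine_rescale(rng):
    values = np.concatenate([rng.normal(30, 5, 900), rng.normal(150, 10, 124)]).reshape(
        32, 32
    )
    mask_a, _ = binarize_yen(_img(values))
    mask_b, _ = binarize_yen(_img(values * 7.3 + 1000.0))
    np.testing.assert_array_equal(mask_a, mask_b)


def test_yen_constant_image_rejected():
    with pytest.raises(ValueError, match="constant"):
        binarize_yen(_img(np.full((8, 8), 3.0)))


# ---------------------------------------------------------------- full chain


def test_preprocess_mask_area_matches_truth_footprint():
    cfg = clean_scene_config(seed=21, pre_density=0.2)
    images, truth = generate_scene(cfg)
    mask = preprocess(images["pre"], FAST_PP)
    # total true footprint at 2 sigma (sigma = radius / 2)
    radii = truth.channels["pre"].radii_um
    truth_area_px = np.pi * (radii / images["pre"].pixel_size_um) ** 2
    assert mask.sum() == pytest.approx(truth_area_px.sum(), rel=0.25)


def test_preprocess_all_background_scene_near_empty_mask():
    from astrodomain import ChannelSpec, SceneConfig

    worst = 0.0
    for seed in range(20):
        cfg = SceneConfig(
            field_size_um=15.0,
            pixel_size_um=0.05,
            channel_specs=(ChannelSpec("pre", density_per_um2=0.0),),
            coloc_fraction=0.0,
            background_level=500.0,
            noise_sd=30.0,
            blob_density_per_um2=0.0,
            seed=seed,
        )
        images, _ = generate_scene(cfg)
        mask = preprocess(images["pre"], FAST_PP)
        worst = max(worst, mask.mean())
    assert worst < 0.005


def test_preprocess_deterministic_and_nonmutating():
    cfg = clean_scene_config(seed=4, pre_density=0.3)
    images, _ = generate_scene(cfg)
    before = images["pre"].values.copy()
    mask_a = preprocess(images["pre"], FAST_PP)
    mask_b = preprocess(images["pre"], FAST_PP)
    np.testing.assert_array_equal(mask_a, mask_b)
    np.testing.assert_array_equal(images["pre"].values, before)


def test_operators_preserve_shape_and_pixel_size():
    img = Image(np.random.default_rng(0).random((40, 40)), 0.07)
    for out in (
        subtract_background(img, 5),
        bandpass(img, 2, 10),
        despeckle(img, 3),
        sharpen(img),
    ):
        assert out.shape == img.shape
        assert out.pixel_size_um == img.pixel_size_um


def test_excluded_pixels_never_enter_mask():
    cfg = clean_scene_config(seed=13, pre_density=0.4)
    images, _ = generate_scene(cfg)
    excluded = np.zeros(images["pre"].shape, dtype=bool)
    excluded[:100, :] = True
    img = Image(images["pre"].values, images["pre"].pixel_size_um, excluded_mask=excluded)
    mask = preprocess(img, FAST_PP)
    assert not mask[excluded].any()


def test_params_validation():
    with pytest.raises(ValueError):
        PreprocessParams(bandpass_small_px=40, bandpass_large_px=3)
    with pytest.raises(ValueError):
        PreprocessParams(despeckle_kernel_px=2)
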