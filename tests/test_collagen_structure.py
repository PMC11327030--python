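"""Fiber architecture: masks, lengths, Lf oracle, FFT metrics."""

import numpy as np
import pytest

from gelquant import collagen_structure as cs
from gelquant import synthetic_data as sd


def make_mask(arr, pixel_size=1.0):
    return cs.BinaryFiberMask(np.asarray(arr, bool), pixel_size, 0.5)


def brute_force_largest_empty_square(fiber):
    """Oracle: exhaustive scan over every square placement and size."""
    h, w = fiber.shape
    best = 0
    for s in range(1, min(h, w) + 1):
        found = False
        for i in range(h - s + 1):
            for j in range(w - s + 1):
                if not fiber[i:i + s, j:j + s].any():
                    found = True
                    break
            if found:
                break
        if found:
            best = s
        else:
            break
    return best


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------


def test_binarize_two_level_image_recovers_fibers_exactly():
    img = np.full((32, 32), 10.0)
    img[10:20, 5:25] = 200.0
    mask = cs.binarize_fibers(cs.FiberImage(img, 0.5), method="otsu")
    np.testing.assert_array_equal(mask.mask, img >= 200.0)


def test_binarize_constant_image_warns_and_returns_empty():
    with pytest.warns(UserWarning, match="degenerate"):
        mask = cs.binarize_fibers(cs.FiberImage(np.full((20, 20), 7.0), 1.0))
    assert not mask.mask.any()
    assert np.isnan(mask.threshold_used)


def test_fixed_threshold_is_consistent_across_batch(rng):
    images = [cs.FiberImage(rng.uniform(0, 255, (24, 24)), 1.0) for _ in range(2)]
    masks = [cs.binarize_fibers(im, "fixed", fixed_threshold=99.0)
             for im in images]
    assert masks[0].threshold_used == masks[1].threshold_used == 99.0
    with pytest.raises(ValueError):
        cs.binarize_fibers(images[0], "fixed")


def test_shg_positive_fraction_hand_cases():
    bright = cs.FiberImage(np.full((16, 16), 200.0), 1.0)
    assert cs.shg_positive_fraction(bright, 100) == 100.0
    dark = cs.FiberImage(np.zeros((16, 16)), 1.0)
    assert cs.shg_positive_fraction(dark, 100) == 0.0
    half = np.zeros((16, 16))
    half[:8] = 200.0
    assert cs.shg_positive_fraction(cs.FiberImage(half, 1.0), 100) == 50.0


# ---------------------------------------------------------------------------
# fiber lengths
# ---------------------------------------------------------------------------


def test_single_segment_length_measured_within_one_pixel():
    mask = np.zeros((64, 64), bool)
    mask[32, 10:50] = True  # 40-pixel horizontal fiber
    lengths = cs.measure_fiber_lengths(make_mask(mask, pixel_size=0.42), seed=0)
    assert len(lengths) == 1
    assert lengths[0] == pytest.approx(40 * 0.42, abs=0.42)


def test_two_disjoint_segments_both_measured():
    mask = np.zeros((64, 64), bool)
    mask[10, 5:15] = True  # 10 px
    mask[40, 5:35] = True  # 30 px
    lengths = cs.measure_fiber_lengths(make_mask(mask), n_samples=2, seed=0)
    assert len(lengths) == 2
    np.testing.assert_allclose(lengths, [9.0, 29.0], atol=1.0)


def test_fiber_length_sampling_is_seeded():
    image, _ = sd.generate_fiber_image(
        sd.FiberFieldSpec(n_fibers=100), sd.SimConfig(seed=4))
    mask = cs.binarize_fibers(image, "fixed", fixed_threshold=60)
    a = cs.measure_fiber_lengths(mask, n_samples=5, seed=11)
    b = cs.measure_fiber_lengths(mask, n_samples=5, seed=11)
    np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError, match="no fiber"):
        cs.measure_fiber_lengths(make_mask(np.zeros((20, 20))))


# ---------------------------------------------------------------------------
# free-space length
# ---------------------------------------------------------------------------


def test_lf_hand_cases():
    assert cs.free_space_length(make_mask(np.zeros((100, 100)))) == 100.0
    assert cs.free_space_length(make_mask(np.ones((100, 100)))) == 0.0
    line = np.zeros((100, 100), bool)
    line[:, 30] = True
    assert cs.free_space_length(make_mask(line)) == 69.0


def test_lf_matches_brute_force_oracle(rng):
    """Exact mode equals exhaustive search on random small masks."""
    for _ in range(50):
        h, w = rng.integers(16, 49, size=2)
        mask = rng.random((h, w)) < rng.uniform(0.01, 0.2)
        assert cs.free_space_length(make_mask(mask)) == \
            brute_force_largest_empty_square(mask)


def test_lf_monotone_under_added_fibers(rng):
    mask = rng.random((64, 64)) < 0.02
    lf0 = cs.free_space_length(make_mask(mask))
    denser = mask.copy()
    extra = rng.random((64, 64)) < 0.05
    denser |= extra
    assert cs.free_space_length(make_mask(denser)) <= lf0


def test_lf_monte_carlo_converges_to_deterministic(rng):
    for _ in range(10):
        mask = rng.random((64, 64)) < 0.03
        det = cs.free_space_length(make_mask(mask))
        mc = cs.free_space_length(make_mask(mask), mode="monte_carlo",
                                  n_draws=20_000, seed=1)
        assert abs(mc - det) <= 1.0


def test_lf_modal_criterion_is_not_larger_than_exact(rng):
    """The plurality-based reading settles at or below the exact Lf."""
    mask = rng.random((80, 80)) < 0.01
    det = cs.free_space_length(make_mask(mask))
    modal = cs.free_space_length(make_mask(mask), mode="monte_carlo",
                                 n_draws=5_000, seed=2, criterion="modal")
    assert modal <= det


# ---------------------------------------------------------------------------
# FFT power spectrum
# ---------------------------------------------------------------------------


def _stripes(period=10, duty=0.3, n=100, lo=10.0, hi=200.0):
    """Vertical stripes: intensity varies along x (columns)."""
    on = int(round(duty * period))
    pattern = np.array([hi] * on + [lo] * (period - on))
    return np.tile(pattern, (n, n // period))


def test_constant_image_has_no_power():
    spec = cs.fft_power_spectrum(cs.FiberImage(np.full((32, 32), 9.0), 1.0),
                                 window="none")
    assert spec.max() < 1e-12


def test_stripes_peak_at_expected_frequency():
    img = cs.FiberImage(_stripes(period=10), 1.0)
    spec = cs.fft_power_spectrum(img, window="none")
    cy, cx = np.array(spec.shape) // 2
    spec[cy, cx] = 0.0  # residual DC
    peak = np.unravel_index(np.argmax(spec), spec.shape)
    assert peak[0] == cy  # on the horizontal frequency axis
    assert abs(abs(peak[1] - cx) / spec.shape[1] - 0.1) < 1e-9


def test_parseval_identity():
    rng = np.random.default_rng(0)
    img = cs.FiberImage(rng.normal(100, 20, (64, 64)), 1.0)
    spec = cs.fft_power_spectrum(img, window="none")
    lhs = np.sum((img.data - img.data.mean()) ** 2)
    assert spec.sum() / img.data.size == pytest.approx(lhs, rel=1e-6)


# ---------------------------------------------------------------------------
# anisotropy ellipse
# ---------------------------------------------------------------------------


def test_horizontal_stripes_report_horizontal_fibers():
    img = cs.FiberImage(_stripes().T.copy(), 1.0)  # varies along y
    ratio, orientation = cs.anisotropy_ellipse(cs.fft_power_spectrum(img))
    assert abs(orientation - 0.0) < 5.0
    assert ratio > 5.0


def test_isotropic_field_has_low_anisotropy():
    ratios = []
    for seed in range(20):
        image, _ = sd.generate_fiber_image(
            sd.FiberFieldSpec(n_fibers=120, orientation_kappa=0.0),
            sd.SimConfig(seed=seed))
        ratios.append(cs.anisotropy_ellipse(cs.fft_power_spectrum(image))[0])
    assert np.mean(ratios) < 1.3


def test_anisotropy_invariant_under_90_degree_rotation():
    image, _ = sd.generate_fiber_image(
        sd.FiberFieldSpec(n_fibers=80, orientation_kappa=20.0,
                          orientation_mean_deg=30.0),
        sd.SimConfig(seed=6))
    r1, o1 = cs.anisotropy_ellipse(cs.fft_power_spectrum(image))
    rotated = cs.FiberImage(np.rot90(image.data).copy(), image.pixel_size)
    r2, o2 = cs.anisotropy_ellipse(cs.fft_power_spectrum(rotated))
    assert r2 == pytest.approx(r1, rel=0.02)
    # circular distance between the two orientations must be ~90°
    shift = abs(((o2 - o1) + 90.0) % 180.0 - 90.0)
    assert shift == pytest.approx(90.0, abs=5.0)


# ---------------------------------------------------------------------------
# radial size profile
# ---------------------------------------------------------------------------


def test_stripe_pattern_pore_and_fiber_sizes():
    img = cs.FiberImage(_stripes(period=10, duty=0.3), 1.0)
    spec = cs.fft_power_spectrum(img, window="none")
    frac = cs.shg_positive_fraction(img, 100.0) / 100.0
    pore, fiber = cs.radial_size_profile(spec, 1.0, frac)
    assert fiber == pytest.approx(3.0, rel=0.05)
    assert pore == pytest.approx(7.0, rel=0.05)


def test_noise_image_has_no_characteristic_scale(rng):
    img = cs.FiberImage(rng.normal(50, 10, (64, 64)), 1.0)
    pore, fiber = cs.radial_size_profile(
        cs.fft_power_spectrum(img, window="none"), 1.0, 0.1)
    assert np.isnan(pore) and np.isnan(fiber)


def test_denser_field_has_smaller_pores():
    pores = {50: [], 500: []}
    for seed in range(10):
        cfg = sd.SimConfig(seed=seed)
        for n in pores:
            image, _ = sd.generate_fiber_image(
                sd.FiberFieldSpec(n_fibers=n), cfg)
            spec = cs.fft_power_spectrum(image)
            frac = cs.shg_positive_fraction(image, 60.0) / 100.0
            pores[n].append(cs.radial_size_profile(spec, cfg.pixel_size, frac)[0])
    assert np.nanmean(pores[500]) < np.nanmean(pores[50])


def test_structure_metrics_end_to_end():
    image, _ = sd.generate_fiber_image(
        sd.FiberFieldSpec(n_fibers=100), sd.SimConfig(seed=3))
    m = cs.structure_metrics(image, threshold_method="fixed",
                             fixed_threshold=60.0, seed=0)
    assert m.lf <= image.data.shape[0] * image.pixel_size
    assert m.anisotropy_ratio >= 1.0
    assert 0.0 <= m.shg_positive_fraction <= 100.0
    assert len(m.fiber_lengths) == 20
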