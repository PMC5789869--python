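import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semqc.errors import EmptyHistogramError, ValidationError
from semqc.histogram_metrics import (
    AcquisitionTransform,
    IntensityHistogram,
    TwoGaussianFit,
    TwoGaussianModel,
    _f_two_gauss,
    cnr,
    compute_histogram,
    fit_two_gaussians,
    michelson_halfwidth,
    rescale_image,
)
from semqc.io import GrayscaleImage

from conftest import mixture_counts


# --- compute_histogram ----------------------------------------------------

def test_histogram_counts_pixels_exactly():
    img = GrayscaleImage(np.array([[0, 0], [255, 255]], np.uint8), 8)
    h = compute_histogram(img)
    assert h.levels.size == 256
    assert h.counts[0] == 2 and h.counts[255] == 2 and h.n_pixels == 4

    const = GrayscaleImage(np.full((5, 5), 7, np.uint8), 8)
    hc = compute_histogram(const)
    assert hc.counts[7] == 25 and hc.counts.sum() == 25
    assert (np.nonzero(hc.counts)[0] == [7]).all()


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, derandomize=True, deadline=None)
def test_histogram_conserves_pixel_count(seed):
    rng = np.random.default_rng(seed)
    px = rng.integers(0, 256, size=(17, 13)).astype(np.uint8)
    h = compute_histogram(GrayscaleImage(px, 8))
    assert h.n_pixels == px.size


# --- michelson_halfwidth --------------------------------------------------

def test_michelson_hand_checked_cases():
    levels = np.arange(256)

    spike = np.zeros(256, int)
    spike[128] = 10
    res = michelson_halfwidth(IntensityHistogram(levels, spike))
    assert (res.l_min, res.l_max, res.contrast) == (128, 128, 0.0)

    uniform = np.full(256, 3)
    res = michelson_halfwidth(IntensityHistogram(levels, uniform))
    assert (res.l_min, res.l_max) == (0, 255) and res.contrast == 1.0

    counts = np.zeros(256, int)
    counts[100], counts[150], counts[200] = 80, 100, 80
    res = michelson_halfwidth(IntensityHistogram(levels, counts))
    assert (res.l_min, res.l_max) == (100, 200)
    assert res.contrast == pytest.approx(100 / 300)


def test_michelson_degenerate_at_zero_errors():
    counts = np.zeros(256, int)
    counts[0] = 10
    with pytest.raises(EmptyHistogramError):
        michelson_halfwidth(IntensityHistogram(np.arange(256), counts))


@given(st.integers(0, 2**31 - 1), st.integers(2, 9))
@settings(max_examples=30, derandomize=True, deadline=None)
def test_michelson_in_unit_interval_and_count_scale_invariant(seed, k):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 100, size=64)
    counts[rng.integers(0, 64)] += 1  # ensure nonzero
    hist = IntensityHistogram(np.arange(1, 65), counts)
    res = michelson_halfwidth(hist)
    assert 0.0 <= res.contrast <= 1.0
    scaled = michelson_halfwidth(IntensityHistogram(np.arange(1, 65), counts * k))
    assert (scaled.l_min, scaled.l_max, scaled.contrast) == (res.l_min, res.l_max, res.contrast)


def test_michelson_gray_shift_covariance():
    counts = np.zeros(256, int)
    counts[100], counts[150], counts[200] = 80, 100, 80
    base = michelson_halfwidth(IntensityHistogram(np.arange(256), counts))
    shifted = michelson_halfwidth(IntensityHistogram(np.arange(256) + 10, counts))
    assert (shifted.l_min, shifted.l_max) == (base.l_min + 10, base.l_max + 10)
    assert shifted.contrast == pytest.approx((200 - 100) / (210 + 110))


# --- fit_two_gaussians ----------------------------------------------------

def test_noiseless_fit_is_exact_fixed_point(bimodal_hist):
    hist, truth = bimodal_hist
    fit = fit_two_gaussians(hist)
    for key in truth:
        assert getattr(fit, key) == pytest.approx(truth[key], rel=1e-3)
    assert fit.residual < 1e-6 * hist.n_pixels**2
    assert not fit.degenerate


def test_fit_accepts_explicit_init(bimodal_hist):
    hist, truth = bimodal_hist
    init = TwoGaussianFit(400, 70, 80, 1800, 190, 160, residual=np.inf)
    fit = fit_two_gaussians(hist, init=init)
    assert fit.mean_b == pytest.approx(truth["mean_b"], rel=1e-3)


def test_single_gaussian_histogram_flagged_degenerate():
    levels = np.arange(256)
    counts = np.round(3000 * np.exp(-((levels - 128.0) ** 2) / (2 * 100))).astype(int)
    fit = fit_two_gaussians(IntensityHistogram(levels, counts))
    assert fit.degenerate


def test_fit_requires_six_nonzero_bins():
    counts = np.zeros(256, int)
    counts[[10, 50, 90, 130, 170]] = 5
    with pytest.raises(ValidationError):
        fit_two_gaussians(IntensityHistogram(np.arange(256), counts))


def _lattice_best_residual(levels, counts):
    """Brute-force oracle: coarse lattice over means/SDs, amplitudes by
    linear least squares, returning the best residual found."""
    best = np.inf
    sds = [2.0, 4.0, 8.0, 16.0]
    means = np.arange(levels.min(), levels.max() + 1, 4.0)
    for i, m1 in enumerate(means):
        for m2 in means[i:]:
            for s1 in sds:
                for s2 in sds:
                    basis = np.column_stack([
                        np.exp(-((levels - m1) ** 2) / (2 * s1**2)),
                        np.exp(-((levels - m2) ** 2) / (2 * s2**2)),
                    ])
                    amps, *_ = np.linalg.lstsq(basis, counts, rcond=None)
                    amps = np.clip(amps, 0, None)
                    resid = float(np.sum((basis @ amps - counts) ** 2))
                    best = min(best, resid)
    return best


def test_fit_beats_brute_force_lattice_on_small_histograms():
    levels = np.arange(64)
    params = dict(amp_m=300.0, mean_m=18.0, var_m=16.0, amp_b=900.0, mean_b=44.0, var_b=36.0)
    rng = np.random.default_rng(7)
    counts = mixture_counts(levels, params, rng)
    fit = fit_two_gaussians(IntensityHistogram(levels, counts))
    oracle = _lattice_best_residual(levels.astype(float), counts.astype(float))
    assert fit.residual <= oracle * 1.01


# --- cnr ------------------------------------------------------------------

def test_cnr_formula_and_zero_contrast():
    fit = TwoGaussianFit(500, 80, 100, 2000, 180, 144, residual=0.0)
    assert cnr(fit) == pytest.approx(100 / 144)
    flat = TwoGaussianFit(500, 90, 100, 2000, 90, 144, residual=0.0)
    assert cnr(flat) == 0.0


@given(st.floats(0.1, 10), st.floats(-50, 50))
@settings(max_examples=50, derandomize=True, deadline=None)
def test_cnr_invariant_under_acquisition_model(a, o):
    fit = TwoGaussianFit(500, 80, 100, 2000, 180, 144, residual=0.0)
    moved = fit.transformed(AcquisitionTransform(amplification=a, offset=o))
    assert cnr(moved) == pytest.approx(cnr(fit), rel=1e-12)


# --- rescale_image --------------------------------------------------------

def test_rescale_identity_scaling_and_clipping(caplog):
    px = np.array([[10, 100], [130, 200]], np.uint8)
    img = GrayscaleImage(px, 8)
    same = rescale_image(img, AcquisitionTransform(1.0, 0.0))
    np.testing.assert_array_equal(same.pixels, px)

    small = GrayscaleImage(np.array([[50, 100]], np.uint8), 8)
    doubled = rescale_image(small, AcquisitionTransform(2.0, 0.0))
    assert doubled.pixels.max() == 200

    import logging

    with caplog.at_level(logging.WARNING, logger="semqc.histogram_metrics"):
        clipped = rescale_image(img, AcquisitionTransform(2.0, 0.0))
    assert (clipped.pixels[px >= 128] == 255).all()
    assert any("clipped" in r.message for r in caplog.records)
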