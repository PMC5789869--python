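"""Histogram-level image-quality statistics for SEM micrographs.

The model: the intensity histogram of a membrane-stained EM micrograph is a
mixture of two populations — membrane pixels (the darker peak of an inverted
positive image) and background pixels (the brighter peak).  Fitting

    f(x) = A exp(-(x - Vm)^2 / (2 σvm²)) + B exp(-(x - Vb)^2 / (2 σvb²))

to the histogram yields peak positions (Vm, Vb) and noise variances
(σvm², σvb²), from which the contrast-to-noise ratio is

    CNR = (Vb - Vm) / σvb²

Note the denominator is the background-peak *variance*, not its standard
deviation; this differs from the conventional CNR definition and is kept as
is.  Under the acquisition model Vm = a·Nm − o, Vb = a·Nb − o,
σvb² = a·σb², CNR is invariant to both amplification a and offset o, which
is what makes it comparable across detector/contrast settings.  (If
variances scaled as a² — the scaling a physical intensity gain would
produce — CNR would only be offset-invariant; the linear-in-a model is the
one implemented.)

Michelson contrast is evaluated at the half-width of the histogram: with h
half of the global maximum count, Lmin and Lmax are the outermost gray
levels whose count still reaches h, and contrast = (Lmax−Lmin)/(Lmax+Lmin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator

from .errors import EmptyHistogramError, FitError, ValidationError
from .io import GrayscaleImage

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityHistogram",
    "HalfWidthContrast",
    "TwoGaussianFit",
    "AcquisitionTransform",
    "TwoGaussianModel",
    "compute_histogram",
    "michelson_halfwidth",
    "fit_two_gaussians",
    "cnr",
    "rescale_image",
]


@dataclass(frozen=True)
class IntensityHistogram:
    """Pixel counts per gray level for one micrograph."""

    levels: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        levels = np.asarray(self.levels, dtype=np.int64)
        counts = np.asarray(self.counts)
        if levels.ndim != 1 or counts.shape != levels.shape:
            raise ValidationError("levels and counts must be matching 1-D arrays")
        if levels.size and (np.diff(levels) <= 0).any():
            raise ValidationError("gray levels must be strictly increasing")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.array_equal(counts, np.round(counts)):
                raise ValidationError("histogram counts must be integers")
            counts = counts.astype(np.int64)
        if counts.size == 0 or (counts < 0).any():
            raise ValidationError("histogram counts must be non-negative and non-empty")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "IntensityHistogram":
        """Build from a validated ``histogram`` CSV table (gray_level,count)."""
        order = np.argsort(df["gray_level"].to_numpy())
        return cls(df["gray_level"].to_numpy()[order], df["count"].to_numpy()[order])


@dataclass(frozen=True)
class HalfWidthContrast:
    """Michelson contrast at the histogram half-width crossings."""

    l_min: int
    l_max: int
    contrast: float


@dataclass(frozen=True)
class AcquisitionTransform:
    """Contrast/brightness adjustment applied during imaging: x → a·x − o."""

    amplification: float = 1.0
    offset: float = 0.0

    def __post_init__(self):
        if self.amplification <= 0:
            raise ValidationError("amplification must be positive")


@dataclass(frozen=True)
class TwoGaussianFit:
    """Fitted membrane/background mixture parameters.

    The membrane component is, by convention, the lower-mean one
    (membrane is black in an inverted positive image); components are
    swapped after fitting if needed.  ``residual`` is the sum of squared
    residuals of f(x) against the counts.  ``degenerate`` is raised when
    either component holds < 1% of the pixels or the peaks are closer than
    one gray level — i.e. the histogram is effectively single-peaked.
    """

    amp_m: float
    mean_m: float
    var_m: float
    amp_b: float
    mean_b: float
    var_b: float
    residual: float
    degenerate: bool = False

    def __post_init__(self):
        if self.var_m <= 0 or self.var_b <= 0:
            raise ValidationError("fitted variances must be positive")
        if self.mean_m > self.mean_b:
            raise ValidationError("membrane mean must not exceed background mean")

    def transformed(self, t: AcquisitionTransform) -> "TwoGaussianFit":
        """Apply the acquisition model: means → a·V − o, variances → a·σ²."""
        a, o = t.amplification, t.offset
        return TwoGaussianFit(
            amp_m=self.amp_m, mean_m=a * self.mean_m - o, var_m=a * self.var_m,
            amp_b=self.amp_b, mean_b=a * self.mean_b - o, var_b=a * self.var_b,
            residual=self.residual, degenerate=self.degenerate,
        )


def compute_histogram(image: GrayscaleImage) -> IntensityHistogram:
    """Histogram with one bin per possible gray level of the bit depth."""
    counts = np.bincount(image.pixels.ravel(), minlength=image.n_levels)
    return IntensityHistogram(np.arange(image.n_levels), counts)


def michelson_halfwidth(hist: IntensityHistogram) -> HalfWidthContrast:
    """Michelson contrast at the half-width of the histogram.

    With c* the global maximum count and h = c*/2, Lmin is the smallest and
    Lmax the largest gray level whose count reaches h (outermost crossings;
    zero-count gaps in between are ignored).  Contrast is
    (Lmax−Lmin)/(Lmax+Lmin), 0 when the crossings coincide, and undefined
    (error) when they coincide at gray level 0.
    """
    counts = hist.counts
    c_max = counts.max()
    if c_max == 0:
        raise EmptyHistogramError("histogram has no counts")
    half = c_max / 2.0
    at_half = np.nonzero(counts >= half)[0]
    l_min = int(hist.levels[at_half[0]])
    l_max = int(hist.levels[at_half[-1]])
    if l_max == l_min:
        if l_max == 0:
            raise EmptyHistogramError("half-width collapses to gray level 0; contrast undefined")
        return HalfWidthContrast(l_min, l_max, 0.0)
    return HalfWidthContrast(l_min, l_max, (l_max - l_min) / (l_max + l_min))


def _f_two_gauss(x, amp1, mean1, sd1, amp2, mean2, sd2):
    return amp1 * np.exp(-((x - mean1) ** 2) / (2 * sd1**2)) + amp2 * np.exp(
        -((x - mean2) ** 2) / (2 * sd2**2)
    )


class TwoGaussianModel(BaseEstimator):
    """Two-Gaussian histogram mixture fitted by nonlinear least squares.

    scikit-learn style estimator: ``fit(levels, counts)`` fits f(x) to the
    histogram; ``predict(levels)`` evaluates the fitted curve.  Fitted
    attributes carry trailing underscores (``mean_m_``, ``var_b_``, ...).

    Parameters
    ----------
    n_restarts : int
        Additional fits from jittered initial peak positions (the
        initialisation itself comes from an Otsu split of the histogram);
        the best-residual solution wins.
    random_state : int
        Seed for the jitter; fixed so fits are reproducible.
    """

    def __init__(self, n_restarts: int = 5, random_state: int = 0):
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- initial guess from an Otsu split ---------------------------------
    @staticmethod
    def _moments(levels, counts):
        n = counts.sum()
        if n == 0 or (counts > 0).sum() == 0:
            return None
        mean = float(np.average(levels, weights=counts))
        var = float(np.average((levels - mean) ** 2, weights=counts))
        return n, mean, max(var, 0.25)

    def _initial_guess(self, levels, counts):
        try:
            thr = threshold_otsu(hist=(counts.astype(float), levels.astype(float)))
        except Exception:
            thr = float(np.average(levels, weights=counts))
        left = levels <= thr
        lo = self._moments(levels[left], counts[left])
        hi = self._moments(levels[~left], counts[~left])
        if lo is None or hi is None:
            n, mean, var = self._moments(levels, counts)
            sd = np.sqrt(var)
            lo = (n / 2, mean - sd, var)
            hi = (n / 2, mean + sd, var)
        guesses = []
        for (n1, m1, v1), (n2, m2, v2) in [(lo, hi)]:
            a1 = n1 / np.sqrt(2 * np.pi * v1)
            a2 = n2 / np.sqrt(2 * np.pi * v2)
            guesses.append([a1, m1, np.sqrt(v1), a2, m2, np.sqrt(v2)])
        return guesses[0]

    def fit(self, levels, counts, init: TwoGaussianFit | None = None):
        levels = np.asarray(levels, dtype=float).ravel()
        counts = np.asarray(counts, dtype=float).ravel()
        if (counts > 0).sum() < 6:
            raise ValidationError(
                "two-Gaussian fit needs >= 6 nonzero bins (6 free parameters)"
            )
        n_pixels = counts.sum()
        span = levels.max() - levels.min() + 1.0
        lower = [0.0, levels.min() - span, 1e-3, 0.0, levels.min() - span, 1e-3]
        upper = [
            2 * counts.max() + 1, levels.max() + span, 2 * span,
            2 * counts.max() + 1, levels.max() + span, 2 * span,
        ]
        if init is not None:
            p0 = [init.amp_m, init.mean_m, np.sqrt(init.var_m),
                  init.amp_b, init.mean_b, np.sqrt(init.var_b)]
        else:
            p0 = self._initial_guess(levels, counts)
        rng = np.random.default_rng(self.random_state)
        best = None
        p0s = [p0]
        for _ in range(self.n_restarts):
            jit = list(p0)
            jit[1] += rng.normal(0, 0.05 * span)
            jit[4] += rng.normal(0, 0.05 * span)
            p0s.append(jit)
        for guess in p0s:
            guess = np.clip(guess, lower, upper)
            try:
                popt, _ = curve_fit(
                    _f_two_gauss, levels, counts, p0=guess,
                    bounds=(lower, upper), maxfev=20000,
                )
            except (RuntimeError, ValueError):
                continue
            resid = float(np.sum((_f_two_gauss(levels, *popt) - counts) ** 2))
            if best is None or resid < best[1]:
                best = (popt, resid)
        if best is None:
            raise FitError("two-Gaussian fit did not converge from any start")
        popt, resid = best
        comps = sorted(
            [(popt[1], popt[0], popt[2] ** 2), (popt[4], popt[3], popt[5] ** 2)]
        )
        (m_mean, m_amp, m_var), (b_mean, b_amp, b_var) = comps
        # component pixel mass = amp * sqrt(2 pi var)
        w_m = m_amp * np.sqrt(2 * np.pi * m_var)
        w_b = b_amp * np.sqrt(2 * np.pi * b_var)
        degenerate = (
            min(w_m, w_b) < 0.01 * n_pixels or abs(b_mean - m_mean) < 1.0
        )
        self.amp_m_, self.mean_m_, self.var_m_ = float(m_amp), float(m_mean), float(m_var)
        self.amp_b_, self.mean_b_, self.var_b_ = float(b_amp), float(b_mean), float(b_var)
        self.residual_ = resid
        self.degenerate_ = bool(degenerate)
        return self

    def predict(self, levels):
        levels = np.asarray(levels, dtype=float)
        return _f_two_gauss(
            levels,
            self.amp_m_, self.mean_m_, np.sqrt(self.var_m_),
            self.amp_b_, self.mean_b_, np.sqrt(self.var_b_),
        )

    def result_(self) -> TwoGaussianFit:
        return TwoGaussianFit(
            amp_m=self.amp_m_, mean_m=self.mean_m_, var_m=self.var_m_,
            amp_b=self.amp_b_, mean_b=self.mean_b_, var_b=self.var_b_,
            residual=self.residual_, degenerate=self.degenerate_,
        )


def fit_two_gaussians(
    hist: IntensityHistogram, init: TwoGaussianFit | None = None
) -> TwoGaussianFit:
    """Fit the membrane/background mixture to a histogram.

    Initialised from an Otsu split of the histogram with up to 5 jittered
    restarts (fixed seed); components are ordered so the membrane mean is
    the lower one.  Single-peak histograms converge but come back with
    ``degenerate=True`` rather than an error.
    """
    model = TwoGaussianModel().fit(hist.levels, hist.counts, init=init)
    return model.result_()


def cnr(fit: TwoGaussianFit) -> float:
    """Contrast-to-noise ratio (Vb − Vm)/σvb² on the stored gray scale."""
    if fit.var_b <= 0:
        raise ValidationError("background variance must be positive for CNR")
    return (fit.mean_b - fit.mean_m) / fit.var_b


def rescale_image(image: GrayscaleImage, transform: AcquisitionTransform) -> GrayscaleImage:
    """Apply x → round(a·x − o) per pixel, clipped to the bit-depth range.

    The fraction of clipped pixels is logged as a warning when nonzero.
    """
    a, o = transform.amplification, transform.offset
    mapped = np.round(a * image.pixels.astype(float) - o)
    top = image.n_levels - 1
    clipped = float(np.mean((mapped < 0) | (mapped > top)))
    if clipped > 0:
        logger.warning("rescale_image clipped %.1f%% of pixels", 100 * clipped)
    out = np.clip(mapped, 0, top).astype(image.pixels.dtype)
    return GrayscaleImage(out, image.bit_depth, image.pixel_size_nm)
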