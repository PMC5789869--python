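# Methods

## Two-Gaussian histogram model and CNR

The intensity histogram of a membrane-stained EM micrograph is treated as
the superposition of two Gaussian components,

    f(x) = A·exp(−(x−Vm)²/2σvm²) + B·exp(−(x−Vb)²/2σvb²),

membrane (lower mean, dark in an inverted positive image) and background
(higher mean).  `fit_two_gaussians` minimises the unweighted sum of
squared residuals of f(x) against the per-level counts over every level
of the bit depth.

*Initialisation.* The histogram is split at its Otsu threshold; each
side's count mass, weighted mean and weighted variance seed one
component.  Up to 5 restarts jitter the two initial means by 5% of the
level span (fixed seed 0); the lowest-residual solution wins.  Bounds
keep amplitudes non-negative and SDs positive.  After fitting, components
are sorted so the membrane component is the lower-mean one.

*Degeneracy.* A fit is flagged (not failed) when either component's pixel
mass A·√(2πσ²) is below 1% of the pixels, or the peaks are closer than
one gray level — the signature of an effectively unimodal histogram.
Downstream consumers decide what to do with flagged fits.

*CNR.* CNR = (Vb − Vm)/σvb².  The denominator is the background-peak
**variance**, not its standard deviation; conventional CNR uses the SD,
and users comparing against other tools should divide accordingly.  The
acquisition model is Vm = a·Nm − o, Vb = a·Nb − o, σvm² = a·σm²,
σvb² = a·σb²: variances scale *linearly* in the amplification, which is
what makes CNR exactly invariant to (a, o).  A physical intensity gain
would scale variances by a², under which CNR is only offset-invariant;
the linear model is implemented as defined and the distinction is left
visible here rather than silently "corrected".

## Michelson contrast at the histogram half-width

"Half width" is read in the simplest way that is well defined for a
bimodal histogram: h is half of the single global maximum count, and
Lmin/Lmax are the outermost gray levels whose count still reaches h.
Zero-count gaps between crossings are ignored, which keeps the rule
stable for sparse 16-bit histograms; no sub-bin interpolation is done.
An alternative per-peak FWHM reading exists but is not implemented; the
global rule is documented so the two can be compared externally.
Contrast is 0 when the crossings coincide and an error when they coincide
at level 0.

## Electron dose

dose (e⁻ nm⁻²) = I · (1/e) · t_dwell / s², with the elementary charge
fixed at 1.60217657 × 10⁻¹⁹ C so worked values are bit-reproducible
rather than tracking CODATA revisions.  Cumulative dose multiplies by the
exposure count; total current multiplies by the beam count.  Dose is
linear in current and dwell and scales as s⁻²; these scaling laws are
asserted as property tests.  Display rounding defaults to 3 significant
figures.

## Conductivity

σ = 1/(Rs·t).  The default thickness is the 50 µm PET core of CNT-coated
tape; it is overridable because which thickness enters the published
arithmetic (full core vs the ~2 µm conductive coat) is a physical
judgment call — the package follows the core-thickness convention.  The
percent reduction between two measurements, 100·(1 − Rs_before/Rs_after),
is independent of thickness and requires matching thicknesses as a sanity
check.  Note that with Rs = 257 Ω ◻⁻¹ and t = 50 µm the formula gives
77.8 S m⁻¹ at 3 significant figures; a published value of 77.9 for these
rounded inputs implies an unrounded resistance mean near 256.7 Ω ◻⁻¹.
The package reports what the formula yields.

## BSE signal efficiency

SE(%) = (BSE0 − BSE_T)·100/BSE0 on a depth histogram with uniform bins
from 0 (default width 10 nm): BSE0 is the surface bin's count and BSE_T
the count of the bin starting at the section thickness T.  The formula is
applied literally to the two bins (`mode="bins"`).  Because the verbal
definition — the proportion of backscattered signal originating within
the section among all of it — is a cumulative statement, a
`mode="cumulative"` option reports the fraction of total counts in bins
starting above T; the two agree exactly only for exponential profiles.
Neither mode interpolates: a thickness that is not a bin start raises an
error instead of silently changing the statistic.  SE is invariant under
scaling all counts and lies in [0, 100] whenever counts are
non-increasing with depth.

## Immunogold density classification

Density is particle count / profile area (µm⁻²).  A bouton is
GABA-positive iff its density is **strictly above** 30 µm⁻², following
the defining wording; a density of exactly 30 classifies negative.
Population summaries report per-predicted-class n, mean and sample SD
(n−1 denominator; undefined below n = 2).  Serial consistency requires
every section of a bouton to classify identically; a tied majority vote
is flagged inconsistent rather than broken, since no tie rule is
published.

## Synthetic data

The generators reproduce the *statistical* structure the analyses
consume, nothing more:

- **Membrane images** — random dilated ellipse perimeters (~2–3 px wide)
  accumulated to a target area fraction (default 0.2 of a 512² canvas),
  membrane intensities N(80, 100), background N(180, 144) on an 8-bit
  scale, then round(a·x − o) with clipping.  The geometry is not
  biological; only the histogram matters downstream.  Fractions above 0.9
  are rejected as infeasible for curve-like masks, and the smallest
  realisable fraction is one curve, so very small requested fractions
  overshoot slightly (the truth record carries the realised fraction).
- **Bouton tables** — per-bouton true densities from class normals
  truncated at zero (defaults: negative 2.0 ± 3.8 µm⁻², n = 245;
  positive 59.7 ± 18.9 µm⁻², n = 48; 3 sections per bouton), per-section
  Poisson(density × area) counts with areas uniform on 0.5–2 µm² (a
  typical bouton-profile range).  Because the negative nominal mean sits
  only ~0.5 SD above zero, truncation raises the realised negative mean
  to ≈3.9 µm⁻²; the truth record stores nominal, analytic-truncated and
  realised means, and recovery tests compare against the truncated truth.
  The positive class is ~3 SD from zero, so its truncation bias is
  negligible (<0.05).
- **Depth histograms** — expected counts ∝ exp(−depth/L) multinomially
  sampled to a fixed total (default 10⁵) in 10 nm bins.  Default decay
  lengths 9.4 nm at 1.5 keV and 28.2 nm at 2 keV give 50 nm-section
  signal efficiencies near 99.5% and 83%, emulating the regime the
  statistic is used in; L must grow with beam energy, which forces SE to
  fall with energy.

Passing tests on these generators show the estimators recover the
parameters of data that *obeys* the model assumptions; they say nothing
about texture, spatial noise correlation, detector nonlinearity or
staining variability in real micrographs.

## Numerical choices

- Fit residuals are reported as absolute sums of squares; the noiseless
  self-consistency test requires residual < 10⁻⁶·(total count)².
- `IntensityHistogram` demands integer, non-negative counts and strictly
  increasing levels; fractional CSV counts are rejected at load.
- Images are kept on their stored scale; 16-bit data is never rescaled
  implicitly.  `rescale_image` rounds, clips to the bit-depth range and
  logs the clipped fraction.
- CLI outputs are written atomically (temp file + rename); metric
  rounding in CLI output is 3 decimals for CNR/Michelson and 3
  significant figures for doses, full precision internally.
- Problem sizes in the test suite (512² images, 10-seed noise studies,
  100-cohort specificity runs) were chosen to keep the full suite around
  ten seconds while leaving Monte-Carlo margins comfortably wide.

## Known limitations

- The half-width contrast rule is one of several defensible readings of
  "half width" for bimodal histograms.
- CNR's variance denominator and the linear-in-a variance scaling are
  followed as defined; both differ from common conventions (SD
  denominator, a² scaling).
- The two-bin SE formula approximates the cumulative proportion it is
  described as; the cumulative mode is provided but neither is asserted
  to be the canonical computational path.
- The gold-particle classifier consumes counts; it does not detect
  particles in images.
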