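# semqc

Quantitative quality control for serial-section scanning electron
microscopy (volume EM / array tomography).

When thousands of ultrathin sections are collected on conductive tape and
imaged in an SEM — single-beam or multi-beam — the practical questions are
always the same: is the image contrast good enough, how much electron dose
is the tissue receiving, is the tape conductive enough to prevent
charging, how much of the backscattered signal actually comes from the
section rather than the substrate, and are density-based labels (such as
post-embedding immunogold) quantifiable and reproducible across serial
sections?  `semqc` packages the small set of statistics that answer these
questions, together with synthetic-data generators so the whole pipeline
can be exercised end to end without microscope data.

## What it computes

**Histogram contrast and CNR.** The intensity histogram of a
membrane-stained micrograph is modeled as two Gaussian populations,
membrane (dark) and background (bright):

    f(x) = A·exp(−(x−Vm)²/2σvm²) + B·exp(−(x−Vb)²/2σvb²)

fitted by nonlinear least squares.  The contrast-to-noise ratio is

    CNR = (Vb − Vm) / σvb²

(the background-peak **variance**, not SD, in the denominator — kept as
defined, see `docs/methods.md`).  Under the acquisition model
Vm = a·Nm − o, Vb = a·Nb − o, σvb² = a·σb², CNR cancels both the
amplification `a` and offset `o`, making it comparable across
brightness/contrast settings.  Michelson contrast
(Lmax − Lmin)/(Lmax + Lmin) is evaluated at the outermost gray levels
whose count reaches half the histogram's maximum.

**Electron dose.** dose (e⁻ nm⁻²) = I · (1/e) · t_dwell / s², with beam
current I (A), dwell time (s), pixel size s (nm); per-beam, cumulative
over repeated exposures, and total multi-beam current.

**Tape conductivity.** σ = 1/(Rs·t) from sheet resistance (Ω ◻⁻¹) and
film thickness, plus the thickness-independent percent conductivity loss
between two measurements.

**BSE signal efficiency.** From a Monte-Carlo escape-depth histogram in
10 nm bins, SE(%) = (BSE0 − BSE_T)·100/BSE0 for a section of thickness T
(50 nm canonical) — the fraction of backscattered signal attributable to
the section.

**Immunogold density classification.** Particles µm⁻² per bouton profile;
GABA-positive iff density > 30 µm⁻² (strictly above); per-population
mean ± SD summaries and serial-section consistency checks.

## Worked example

```python
from semqc import (SyntheticImageSpec, generate_membrane_image,
                   compute_histogram, fit_two_gaussians, cnr,
                   michelson_halfwidth)

img, truth = generate_membrane_image(SyntheticImageSpec(seed=1))
hist = compute_histogram(img)
fit = fit_two_gaussians(hist)
print(f"Vm={fit.mean_m:.2f}  Vb={fit.mean_b:.2f}  var_b={fit.var_b:.2f}")
print(f"CNR = {cnr(fit):.3f}")
c = michelson_halfwidth(hist)
print(f"Lmin={c.l_min} Lmax={c.l_max} michelson={c.contrast:.3f}")
```

prints

```
Vm=79.95  Vb=179.98  var_b=143.15
CNR = 0.699
Lmin=166 Lmax=194 michelson=0.078
```

The generator drew membrane pixels at mean 80 and background at mean 180
with variance 144; the fit recovers them to a fraction of a gray level and
the CNR matches the analytic (180−80)/144 ≈ 0.694.  The Michelson value is
small because the half-width rule sees only the dominant background peak —
exactly the behavior that motivates using CNR alongside it.

The same operations are available from the shell:

```sh
$ semqc dose --current 570e-12 --dwell 100e-9 --pixel 4 --beams 61 --exposures 30
dose_per_beam_e_nm2=22.2
cumulative_dose_e_nm2=667.0
total_current_A=3.48e-08
```

— the per-beam dose of a 61-beam MultiSEM at 570 pA, 100 ns dwell and
4 nm pixels (22.2 e⁻ nm⁻² per exposure, 667 e⁻ nm⁻² over 30 exposures,
~35 nA total current).  Other subcommands: `histogram`, `contrast`,
`cnr`, `conductivity`, `signal-efficiency`, `classify-boutons`, and
`simulate image|boutons|depth` for synthetic datasets with truth records.

## Layout

- `src/semqc/io.py` — TIFF/PNG images, validated CSV schemas
- `src/semqc/histogram_metrics.py` — histogram, Michelson, two-Gaussian fit, CNR
- `src/semqc/dosimetry.py` — electron-dose arithmetic
- `src/semqc/materials.py` — sheet resistance → conductivity
- `src/semqc/signal_efficiency.py` — BSE depth-histogram statistic
- `src/semqc/particle_density.py` — immunogold density classifier
- `src/semqc/synthetic_data.py` — seeded generators with truth records
- `src/semqc/cli.py` — `semqc` command-line interface
- `docs/methods.md` — models, conventions, numerical choices, limitations
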