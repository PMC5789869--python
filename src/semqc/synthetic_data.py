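"""Synthetic inputs with the statistical structure the analyses assume.

Three generators, all bit-reproducible given (spec, seed), each returning
its dataset together with a truth record so downstream tests never have to
re-derive ground truth from outputs:

* membrane images — random smoothed closed curves (~2 px wide) on a
  background, membrane and background intensities drawn from two normals,
  then passed through the acquisition transform round(a·x − o).  Only the
  histogram statistics matter downstream; no biological geometry is
  attempted.
* bouton tables — two density populations (GABA-negative / -positive).
  Each bouton's true density is drawn from its class normal truncated at
  zero; each section then observes a Poisson(density × area) particle
  count over a uniformly drawn profile area.  Truncation raises the
  effective negative-class mean above the nominal parameter (the nominal
  mean sits only ~0.5 SD above zero); the truth record therefore carries
  both the nominal and the analytic truncated means.
* BSE depth histograms — exponential expected depth profiles
  (∝ exp(−depth/decay_length)) multinomially sampled to a fixed total,
  with decay length growing with beam energy so signal efficiency falls
  with energy by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.draw import ellipse_perimeter
from skimage.morphology import dilation, disk

from .errors import ValidationError
from .io import GrayscaleImage
from .signal_efficiency import DepthHistogram

__all__ = [
    "SyntheticImageSpec",
    "SyntheticBoutonSpec",
    "DepthProfileSpec",
    "generate_membrane_image",
    "generate_boutons",
    "generate_depth_histogram",
    "truncated_normal_mean",
]


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Membrane/background mixture image parameters (gray levels, gray²)."""

    width: int = 512
    height: int = 512
    membrane_fraction: float = 0.2
    mean_m: float = 80.0
    mean_b: float = 180.0
    var_m: float = 100.0
    var_b: float = 144.0
    amplification: float = 1.0
    offset: float = 0.0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.membrane_fraction < 1):
            raise ValidationError("membrane_fraction must lie in (0, 1)")
        if self.membrane_fraction > 0.9:
            raise ValidationError("membrane_fraction > 0.9 is infeasible for curve-like masks")
        if self.mean_m >= self.mean_b:
            raise ValidationError("membrane mean must be below background mean")
        if self.var_m <= 0 or self.var_b <= 0:
            raise ValidationError("variances must be positive")
        if self.amplification <= 0:
            raise ValidationError("amplification must be positive")
        if self.bit_depth not in (8, 16):
            raise ValidationError("bit_depth must be 8 or 16")


@dataclass(frozen=True)
class SyntheticBoutonSpec:
    """Two immunogold density populations, densities in particles µm⁻²."""

    n_negative: int = 245
    n_positive: int = 48
    mean_neg: float = 2.0
    sd_neg: float = 3.8
    mean_pos: float = 59.7
    sd_pos: float = 18.9
    area_range: tuple[float, float] = (0.5, 2.0)
    n_sections_per_bouton: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_negative < 1 or self.n_positive < 1 or self.n_sections_per_bouton < 1:
            raise ValidationError("counts must be positive")
        if self.mean_neg >= self.mean_pos:
            raise ValidationError("negative-class mean must be below positive-class mean")
        if self.sd_neg < 0 or self.sd_pos < 0:
            raise ValidationError("SDs must be non-negative")
        lo, hi = self.area_range
        if lo <= 0 or hi < lo:
            raise ValidationError("area_range must be positive with lo <= hi")


@dataclass(frozen=True)
class DepthProfileSpec:
    """Exponential BSE escape-depth profiles per beam energy."""

    n_bins: int = 30
    bin_width_nm: float = 10.0
    total_bse: int = 100_000
    #: keV → decay length (nm); must increase with energy
    decay_length_nm: dict[float, float] = field(
        default_factory=lambda: {1.5: 9.4, 2.0: 28.2}
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_bins < 2 or self.bin_width_nm <= 0 or self.total_bse <= 0:
            raise ValidationError("need >= 2 bins, positive bin width and total")
        energies = sorted(self.decay_length_nm)
        lengths = [self.decay_length_nm[e] for e in energies]
        if any(l <= 0 for l in lengths):
            raise ValidationError("decay lengths must be positive")
        if any(b <= a for a, b in zip(lengths, lengths[1:])):
            raise ValidationError("decay length must increase with beam energy")


def truncated_normal_mean(mean: float, sd: float, lower: float = 0.0) -> float:
    """Analytic mean of a normal(mean, sd) truncated below at ``lower``."""
    if sd == 0:
        return max(mean, lower)
    a = (lower - mean) / sd
    return float(stats.truncnorm.mean(a, np.inf, loc=mean, scale=sd))


def generate_membrane_image(spec: SyntheticImageSpec) -> tuple[GrayscaleImage, dict]:
    """Render a membrane-curve image and return it with its truth record."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=bool)
    target = spec.membrane_fraction
    # accumulate dilated ellipse perimeters until the mask fraction is reached
    for _ in range(100_000):
        if mask.mean() >= target:
            break
        cy, cx = rng.integers(0, h), rng.integers(0, w)
        ry = int(rng.integers(max(3, h // 20), max(4, h // 3)))
        rx = int(rng.integers(max(3, w // 20), max(4, w // 3)))
        orient = rng.uniform(0, np.pi)
        rr, cc = ellipse_perimeter(int(cy), int(cx), ry, rx, orientation=orient, shape=(h, w))
        curve = np.zeros_like(mask)
        curve[rr, cc] = True
        mask |= dilation(curve, disk(1))
    else:  # pragma: no cover - guard against pathological specs
        raise ValidationError("could not reach requested membrane_fraction")
    values = np.where(
        mask,
        rng.normal(spec.mean_m, np.sqrt(spec.var_m), size=mask.shape),
        rng.normal(spec.mean_b, np.sqrt(spec.var_b), size=mask.shape),
    )
    mapped = np.round(spec.amplification * values - spec.offset)
    top = 2**spec.bit_depth - 1
    pixels = np.clip(mapped, 0, top).astype(np.uint8 if spec.bit_depth == 8 else np.uint16)
    image = GrayscaleImage(pixels, spec.bit_depth)
    truth = {
        "kind": "membrane_image",
        "mean_m": spec.mean_m, "mean_b": spec.mean_b,
        "var_m": spec.var_m, "var_b": spec.var_b,
        "amplification": spec.amplification, "offset": spec.offset,
        "membrane_fraction_target": spec.membrane_fraction,
        "membrane_fraction_realized": float(mask.mean()),
        "n_membrane_pixels": int(mask.sum()),
        "n_pixels": int(mask.size),
        "bit_depth": spec.bit_depth,
        "seed": spec.seed,
    }
    return image, truth


def generate_boutons(spec: SyntheticBoutonSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a two-population bouton table (bouton CSV schema) with labels."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.area_range
    rows = []
    true_densities = {"GABA_negative": [], "GABA_positive": []}
    for label, n, mean, sd in [
        ("GABA_negative", spec.n_negative, spec.mean_neg, spec.sd_neg),
        ("GABA_positive", spec.n_positive, spec.mean_pos, spec.sd_pos),
    ]:
        for i in range(n):
            if sd == 0:
                dens = float(max(mean, 0.0))
            else:
                a = (0.0 - mean) / sd
                dens = float(
                    stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng)
                )
            true_densities[label].append(dens)
            bid = f"{'neg' if label == 'GABA_negative' else 'pos'}_{i:04d}"
            for s in range(spec.n_sections_per_bouton):
                area = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
                count = int(rng.poisson(dens * area))
                rows.append((bid, f"sec_{s:03d}", count, area, label))
    df = pd.DataFrame(
        rows, columns=["bouton_id", "section_id", "particle_count", "area_um2", "label"]
    )
    truth = {
        "kind": "boutons",
        "nominal": {
            "GABA_negative": {"mean": spec.mean_neg, "sd": spec.sd_neg, "n": spec.n_negative},
            "GABA_positive": {"mean": spec.mean_pos, "sd": spec.sd_pos, "n": spec.n_positive},
        },
        "truncated_mean": {
            "GABA_negative": truncated_normal_mean(spec.mean_neg, spec.sd_neg),
            "GABA_positive": truncated_normal_mean(spec.mean_pos, spec.sd_pos),
        },
        "realized_mean_density": {
            k: float(np.mean(v)) for k, v in true_densities.items()
        },
        "true_density_per_bouton": {
            f"{'neg' if k == 'GABA_negative' else 'pos'}_{i:04d}": d
            for k, v in true_densities.items()
            for i, d in enumerate(v)
        },
        "n_sections_per_bouton": spec.n_sections_per_bouton,
        "area_range": list(spec.area_range),
        "seed": spec.seed,
    }
    return df, truth


def generate_depth_histogram(spec: DepthProfileSpec) -> tuple[list[DepthHistogram], dict]:
    """One multinomially sampled exponential depth histogram per energy."""
    rng = np.random.default_rng(spec.seed)
    starts = np.arange(spec.n_bins) * spec.bin_width_nm
    hists = []
    for energy in sorted(spec.decay_length_nm):
        decay = spec.decay_length_nm[energy]
        p = np.exp(-starts / decay)
        p /= p.sum()
        counts = rng.multinomial(spec.total_bse, p)
        hists.append(DepthHistogram(starts, counts, beam_energy_kev=energy))
    truth = {
        "kind": "depth_profiles",
        "decay_length_nm": dict(spec.decay_length_nm),
        "bin_width_nm": spec.bin_width_nm,
        "n_bins": spec.n_bins,
        "total_bse": spec.total_bse,
        "seed": spec.seed,
    }
    return hists, truth
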