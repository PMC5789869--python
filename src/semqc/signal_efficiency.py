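"""Backscattered-electron signal efficiency of a thin section.

A Monte Carlo electron-trajectory simulation (e.g. CASINO) yields a
histogram of BSE escape depths in uniform bins (10 nm by default).  For a
section of thickness T the signal-efficiency statistic is

    SE(%) = (BSE0 − BSE_T) · 100 / BSE0

where BSE0 is the count in the surface bin (0–10 nm) and BSE_T the count in
the bin starting at depth T (for the canonical 50 nm section, the 50–60 nm
bin).  It measures how much of the backscattered signal comes from the
section itself rather than the substrate beneath it; it falls as beam
energy (and hence interaction depth) grows.

The default ``mode="bins"`` evaluates that two-bin formula literally.  A
``mode="cumulative"`` alternative treats each bin as BSEs originating at
depth ≥ its start and reports the fraction of *all* BSEs originating above
T — the proportion the statistic approximates; the two agree only for an
exactly exponential depth profile.  Neither mode interpolates: a thickness
that is not a bin start is an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, EmptyHistogramError, ValidationError

__all__ = ["DepthHistogram", "SEProfile", "se_50nm", "se_profile"]


@dataclass(frozen=True)
class DepthHistogram:
    """BSE counts per uniform escape-depth bin, starting at depth 0."""

    bin_start: np.ndarray
    counts: np.ndarray
    beam_energy_kev: float | None = None

    def __post_init__(self):
        starts = np.asarray(self.bin_start, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if starts.ndim != 1 or counts.shape != starts.shape or starts.size < 2:
            raise ValidationError("need matching 1-D bin_start/counts arrays with >= 2 bins")
        widths = np.diff(starts)
        if starts[0] != 0 or not np.allclose(widths, widths[0]) or widths[0] <= 0:
            raise ValidationError("bins must be uniform and increasing from depth 0")
        if (counts < 0).any():
            raise ValidationError("BSE counts must be non-negative")
        object.__setattr__(self, "bin_start", starts)
        object.__setattr__(self, "counts", counts)

    @property
    def bin_width_nm(self) -> float:
        return float(self.bin_start[1] - self.bin_start[0])

    @classmethod
    def from_table(cls, df: pd.DataFrame, beam_energy_kev: float | None = None) -> "DepthHistogram":
        """Build from a validated ``depth_histogram`` CSV table."""
        order = np.argsort(df["depth_bin_start_nm"].to_numpy())
        return cls(
            df["depth_bin_start_nm"].to_numpy()[order],
            df["count"].to_numpy()[order],
            beam_energy_kev,
        )


@dataclass(frozen=True)
class SEProfile:
    """Signal efficiency per beam energy, plus a monotonicity diagnostic."""

    table: pd.DataFrame  # columns: beam_energy_kev, se_percent
    monotone_decreasing: bool = field(default=True)


def se_50nm(hist: DepthHistogram, section_thickness_nm: float = 50.0, mode: str = "bins") -> float:
    """Signal efficiency (%) for a section of the given thickness.

    ``mode="bins"`` (default): (BSE0 − BSE_T)·100/BSE0 on the surface bin
    and the bin starting at T.  ``mode="cumulative"``: percent of total
    counts in bins starting above (shallower than) T.
    """
    starts = hist.bin_start
    if section_thickness_nm <= 0:
        raise ValidationError("section thickness must be positive")
    hit = np.isclose(starts, section_thickness_nm)
    if not hit.any():
        raise AlignmentError(
            f"section thickness {section_thickness_nm} nm is not a bin start "
            f"(bin width {hist.bin_width_nm} nm); no interpolation is performed"
        )
    if mode == "bins":
        bse0 = hist.counts[0]
        if bse0 == 0:
            raise EmptyHistogramError("surface (0-width) bin has zero BSEs; SE undefined")
        bse_t = hist.counts[int(np.nonzero(hit)[0][0])]
        return float((bse0 - bse_t) * 100.0 / bse0)
    if mode == "cumulative":
        total = hist.counts.sum()
        if total == 0:
            raise EmptyHistogramError("depth histogram has zero total BSEs; SE undefined")
        within = hist.counts[starts < section_thickness_nm].sum()
        return float(within * 100.0 / total)
    raise ValidationError(f"unknown mode {mode!r}; expected 'bins' or 'cumulative'")


def se_profile(
    hists: list[DepthHistogram], thickness_nm: float = 50.0, mode: str = "bins"
) -> SEProfile:
    """Signal efficiency across beam energies.

    Rows are ordered by energy; ``monotone_decreasing`` is False when SE
    ever increases with energy (deeper interaction volumes should only
    lower it).
    """
    if not hists:
        raise ValidationError("need at least one depth histogram")
    rows = [
        (h.beam_energy_kev, se_50nm(h, thickness_nm, mode=mode)) for h in hists
    ]
    rows.sort(key=lambda r: (r[0] is None, r[0]))
    table = pd.DataFrame(rows, columns=["beam_energy_kev", "se_percent"])
    se = table["se_percent"].to_numpy()
    monotone = bool((np.diff(se) <= 0).all()) if len(se) > 1 else True
    return SEProfile(table=table, monotone_decreasing=monotone)
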