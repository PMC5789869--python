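"""Electron-dose and beam-current arithmetic.

The dose delivered to one pixel is the number of beam electrons per unit
area:

    dose (e⁻ nm⁻²) = I · (1/e) · t_dwell / s²

with beam current I in amperes, dwell time t_dwell in seconds, pixel size s
in nm, and e the elementary charge.  The charge constant is fixed at
1.60217657e-19 C so worked values are bit-reproducible.  Multi-beam
microscopes deliver this dose *per beam*; repeated exposures accumulate it
linearly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

#: elementary charge, C per electron (fixed constant, not CODATA-current)
ELEMENTARY_CHARGE = 1.60217657e-19

__all__ = ["DoseParameters", "ELEMENTARY_CHARGE", "electron_dose", "cumulative_dose", "total_beam_current"]


@dataclass(frozen=True)
class DoseParameters:
    """Acquisition parameters for dose accounting.

    beam_current in amperes (per beam), dwell_time in seconds, pixel_size in
    nm; n_beams and n_exposures default to a single-beam, single-exposure
    acquisition.
    """

    beam_current: float
    dwell_time: float
    pixel_size: float
    n_beams: int = 1
    n_exposures: int = 1

    def __post_init__(self):
        if self.beam_current <= 0 or self.dwell_time <= 0 or self.pixel_size <= 0:
            raise ValidationError("beam current, dwell time and pixel size must be positive")
        if int(self.n_beams) != self.n_beams or self.n_beams < 1:
            raise ValidationError("n_beams must be a positive integer")
        if int(self.n_exposures) != self.n_exposures or self.n_exposures < 1:
            raise ValidationError("n_exposures must be a positive integer")


def electron_dose(p: DoseParameters) -> float:
    """Per-beam, per-exposure electron dose in e⁻ nm⁻²."""
    return p.beam_current * (1.0 / ELEMENTARY_CHARGE) * p.dwell_time / p.pixel_size**2


def cumulative_dose(p: DoseParameters) -> float:
    """Total dose in e⁻ nm⁻² accumulated over ``n_exposures`` exposures."""
    return electron_dose(p) * p.n_exposures


def total_beam_current(p: DoseParameters) -> float:
    """Summed current over all beams, in amperes."""
    return p.beam_current * p.n_beams
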