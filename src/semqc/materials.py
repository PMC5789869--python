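"""Sheet-resistance to conductivity conversion for tape substrates.

A thin conductive film with sheet resistance Rs (Ω ◻⁻¹) and thickness t (m)
has bulk conductivity σ = 1/(Rs·t) in S m⁻¹.  For CNT-coated PET tape the
thickness defaults to the 50 µm PET core.  The relative conductivity loss
between two measurements of the same film is independent of thickness:
100·(1 − σ_after/σ_before) = 100·(1 − Rs_before/Rs_after).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

#: default film thickness in meters (50 µm PET tape core)
DEFAULT_THICKNESS_M = 50e-6

__all__ = ["SheetMeasurement", "DEFAULT_THICKNESS_M", "conductivity", "conductivity_reduction"]


@dataclass(frozen=True)
class SheetMeasurement:
    """One sheet-resistance measurement: Rs in Ω ◻⁻¹, thickness in meters."""

    rs: float
    thickness: float = DEFAULT_THICKNESS_M

    def __post_init__(self):
        if self.rs <= 0:
            raise ValidationError("sheet resistance must be positive")
        if self.thickness <= 0:
            raise ValidationError("film thickness must be positive")


def conductivity(m: SheetMeasurement) -> float:
    """Conductivity σ = 1/(Rs·t) in S m⁻¹."""
    return 1.0 / (m.rs * m.thickness)


def conductivity_reduction(before: SheetMeasurement, after: SheetMeasurement) -> float:
    """Percent conductivity loss from ``before`` to ``after``.

    Requires equal thickness (it cancels in the ratio); returns
    100·(1 − σ_after/σ_before).
    """
    if before.thickness != after.thickness:
        raise ValidationError("thickness must match between measurements")
    return 100.0 * (1.0 - conductivity(after) / conductivity(before))
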