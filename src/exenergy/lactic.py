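"""Anaerobic lactic contribution from net blood-lactate accumulation.

Each 1 mmol·l⁻¹ of net lactate accumulation ([La⁻]peak − [La⁻]rest) is taken
as equivalent to 3 ml O2 per kg body mass by default; the equivalent is
configurable (5.3 ml·kg⁻¹·mmol⁻¹·l is another value used in the literature).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .exceptions import ValidationError

#: Default oxygen equivalent of net lactate, ml O2·kg⁻¹ per mmol·l⁻¹.
DEFAULT_O2_EQUIV = 3.0


@dataclass(frozen=True)
class LactateMeasure:
    """Resting and peak lactate (mmol·l⁻¹) with body mass (kg)."""

    la_rest: float
    la_peak: float
    body_mass: float
    o2_equiv: float = DEFAULT_O2_EQUIV

    def __post_init__(self) -> None:
        if self.la_rest < 0 or self.la_peak < 0:
            raise ValidationError("lactate concentrations must be >= 0")
        if self.body_mass <= 0:
            raise ValidationError("body mass must be > 0")
        if self.o2_equiv <= 0:
            raise ValidationError("o2_equiv must be > 0")

    @property
    def la_net(self) -> float:
        """Net lactate accumulation, mmol·l⁻¹ (may be negative)."""
        return self.la_peak - self.la_rest


def compute_lamet(m: LactateMeasure) -> tuple[float, tuple[str, ...]]:
    """Anaerobic lactic contribution in liters of O2, with warnings.

    Returns ``la_net × o2_equiv × body_mass / 1000``. A negative net lactate
    yields a negative volume plus a warning; it is never clamped — the caller
    decides how to handle a data problem.
    """
    lo2 = m.la_net * m.o2_equiv * m.body_mass / 1000.0
    warnings: tuple[str, ...] = ()
    if m.la_net < 0:
        warnings = ("peak lactate below resting lactate (negative net delta)",)
    return lo2, warnings


def pick_peak(samples: Sequence[tuple[str, float]]) -> float:
    """Maximum concentration among post-exercise samples (tag, mmol·l⁻¹)."""
    if not samples:
        raise ValidationError("no post-exercise lactate samples")
    return max(conc for _tag, conc in samples)
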