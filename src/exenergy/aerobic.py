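"""Aerobic energy contribution: baseline-corrected area under the exercise VO2 curve.

The aerobic contribution is the oxygen consumed during exercise above rest,
obtained by trapezoidal integration of the breath-by-breath VO2 record (times
in seconds, VO2 in ml·min⁻¹) and subtraction of the resting-rate volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .series_io import BaselineSpec, BreathSeries, resolve_baseline


@dataclass(frozen=True)
class AerobicResult:
    """Outcome of the aerobic computation, all volumes in liters of O2."""

    gross_area: float
    baseline_volume: float
    net_lo2: float
    duration: float
    warnings: tuple[str, ...] = ()


def integrate_trapezoid(series: BreathSeries) -> float:
    """Trapezoidal integral of VO2 over time, in liters of O2.

    Times are seconds and VO2 is ml·min⁻¹, so each trapezoid carries a /60
    minute conversion; the result is divided by 1000 (ml → L). Irregular
    sampling is handled exactly.
    """
    if len(series) < 2:
        raise ValidationError("need at least 2 samples to integrate")
    area_ml = np.trapezoid(series.vo2, series.times / 60.0)
    return float(area_ml) / 1000.0


def compute_amet(series: BreathSeries, baseline: BaselineSpec) -> AerobicResult:
    """Compute the aerobic contribution for an exercise series.

    The baseline is subtracted as rate × duration rather than sample-by-sample
    (equivalent under the trapezoid rule for a constant rate). A negative net
    value is reported with a warning, never clamped or raised.
    """
    if series.phase != "exercise":
        raise ValidationError("aerobic computation expects an exercise-phase series")
    gross = integrate_trapezoid(series)
    rate = resolve_baseline(baseline)
    baseline_volume = rate * series.duration / 60.0 / 1000.0
    net = gross - baseline_volume
    warnings: tuple[str, ...] = ()
    if net < 0:
        warnings = (
            "net aerobic volume is negative (baseline exceeds exercise VO2)",
        )
    return AerobicResult(
        gross_area=gross,
        baseline_volume=baseline_volume,
        net_lo2=net,
        duration=series.duration,
        warnings=warnings,
    )
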