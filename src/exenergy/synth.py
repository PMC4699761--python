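"""Synthetic breath-by-breath VO2 series with known ground truth.

Real metabolic-cart data are irregularly sampled (one sample per breath,
roughly every 2 s at rest, with breath-to-breath variability in both timing
and amplitude). The generators here emulate that: timestamps are jittered
around a mean inter-breath interval, and multiplicative Gaussian noise is
added to the model curve. First-order kinetics only — no cardiodynamic phase,
no slow-component drift during exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .recovery_fit import ExpFitParams, model_bi, model_mono
from .series_io import BreathSeries


@dataclass(frozen=True)
class ExercisePhase:
    """Plateau amplitude above baseline (ml·min⁻¹), on-time-constant (s; 0 =
    instantaneous step), and exercise duration (s)."""

    amplitude: float
    tau_on: float
    duration: float

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.tau_on < 0 or self.duration <= 0:
            raise ValidationError(
                "require amplitude >= 0, tau_on >= 0, duration > 0"
            )


@dataclass(frozen=True)
class SynthSpec:
    """Ground-truth description of a synthetic test.

    ``recovery`` holds the true off-kinetics parameters (mono or bi).
    ``noise_sd`` is the Gaussian noise standard deviation as a fraction of
    the local signal; ``jitter`` the inter-breath-interval jitter fraction.
    """

    baseline: float = 300.0
    exercise: ExercisePhase = field(
        default_factory=lambda: ExercisePhase(
            amplitude=1500.0, tau_on=30.0, duration=600.0
        )
    )
    recovery: ExpFitParams = field(
        default_factory=lambda: ExpFitParams(
            model="mono", baseline=300.0, A1=1500.0, tau1=45.0, td=5.0
        )
    )
    recovery_duration: float = 600.0
    mean_interval: float = 2.0
    jitter: float = 0.3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValidationError("baseline must be >= 0")
        if self.mean_interval <= 0 or self.recovery_duration <= 0:
            raise ValidationError("intervals and durations must be > 0")
        if not (0 <= self.jitter < 1):
            raise ValidationError("jitter fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def _breath_times(
    rng: np.random.Generator, duration: float, mean: float, jitter: float
) -> np.ndarray:
    n = int(np.ceil(duration / (mean * (1.0 - jitter)))) + 2
    intervals = mean * (1.0 + jitter * rng.uniform(-1.0, 1.0, size=n))
    t = np.concatenate([[0.0], np.cumsum(intervals)])
    return t[t <= duration]


def _add_noise(
    rng: np.random.Generator, signal: np.ndarray, noise_sd: float
) -> np.ndarray:
    if noise_sd == 0:
        return signal.copy()
    noisy = signal * (1.0 + noise_sd * rng.standard_normal(signal.shape))
    return np.maximum(noisy, 0.0)


def simulate_recovery(spec: SynthSpec) -> tuple[BreathSeries, ExpFitParams]:
    """Sample the true off-kinetics model at jittered breath times, plus noise.

    Returns the series and the generating truth; identical seeds give
    identical output.
    """
    rng = np.random.default_rng(spec.seed)
    t = _breath_times(rng, spec.recovery_duration, spec.mean_interval, spec.jitter)
    model = model_mono if spec.recovery.model == "mono" else model_bi
    clean = np.asarray(model(t, spec.recovery), dtype=float)
    vo2 = _add_noise(rng, clean, spec.noise_sd)
    return BreathSeries(times=t, vo2=vo2, phase="recovery"), spec.recovery


def exercise_truth_lo2(spec: SynthSpec) -> float:
    """Closed-form baseline-corrected exercise volume, liters of O2.

    ∫₀ᴰ amplitude·(1 − e^(−t/τ_on)) dt = amplitude·(D − τ_on·(1 − e^(−D/τ_on))),
    divided by 60 (ml·min⁻¹·s → ml) and 1000 (ml → L).
    """
    ex = spec.exercise
    if ex.tau_on == 0:
        area = ex.amplitude * ex.duration
    else:
        area = ex.amplitude * (
            ex.duration - ex.tau_on * (1.0 - np.exp(-ex.duration / ex.tau_on))
        )
    return float(area) / 60.0 / 1000.0


def simulate_exercise(spec: SynthSpec) -> tuple[BreathSeries, float]:
    """Generate an exercise-phase series and its exact net volume in L O2.

    VO2(t) = baseline + amplitude·(1 − e^(−t/τ_on)), noisy and jittered; the
    returned truth is the analytic baseline-corrected integral.
    """
    # derive an independent stream so exercise and recovery noise differ
    rng = np.random.default_rng((spec.seed, 1))
    t = _breath_times(rng, spec.exercise.duration, spec.mean_interval, spec.jitter)
    ex = spec.exercise
    if ex.tau_on == 0:
        clean = np.full_like(t, spec.baseline + ex.amplitude)
    else:
        clean = spec.baseline + ex.amplitude * (1.0 - np.exp(-t / ex.tau_on))
    vo2 = _add_noise(rng, clean, spec.noise_sd)
    return BreathSeries(times=t, vo2=vo2, phase="exercise"), exercise_truth_lo2(spec)


def write_series_tsv(series: BreathSeries, path: str) -> None:
    """Write a series as the two-column TSV the readers consume."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_s\tvo2_ml_min\n")
        for t, v in zip(series.times, series.vo2):
            fh.write(f"{float(t)!r}\t{float(v)!r}\n")
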