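"""Post-exercise VO2 off-kinetics and the anaerobic alactic contribution.

After exercise stops, VO2 decays toward rest along one or two exponential
components (the excess post-exercise oxygen consumption, EPOC). The fast
component indexes phosphocreatine resynthesis; its area, amplitude × time
constant (A1·τ1), is the anaerobic alactic energy contribution.

Models (t in seconds, rates in ml·min⁻¹, baseline fixed, not fitted)::

    mono:  VO2(t) = baseline + A1·exp(−(t − td)/τ1)
    bi:    VO2(t) = baseline + A1·exp(−(t − td)/τ1) + A2·exp(−(t − td)/τ2)

with VO2(t) = baseline + ΣA for t < td (the decay starts after the delay td).
Component 1 is always the fast one: returned bi fits satisfy τ1 < τ2.

The least-squares problem is solved by a damped (trust-region) least-squares
method with bounds A ≥ 0, τ ∈ (1 s, window], td ∈ [0, 60 s]; the bi fit is
started from the mono solution.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DegenerateRecoveryError, InsufficientDataError, ValidationError
from .series_io import BreathSeries

#: Lower bound on a time constant (s); prevents delta-like components.
TAU_MIN = 1.0
#: Upper bound on the time delay (s); longer delays are not physiological
#: for off-kinetics.
TD_MAX = 60.0
#: Smallest admissible starting amplitude (ml·min⁻¹).
A_FLOOR = 1.0

MIN_SAMPLES_MONO = 5
MIN_SAMPLES_BI = 7


@dataclass(frozen=True)
class ExpFitParams:
    """Parameters of the off-kinetics model plus fit diagnostics.

    ``baseline`` is fixed (taken from the exercise phase), never fitted.
    For mono fits ``A2`` and ``tau2`` are ``None``.
    """

    model: str  # "mono" | "bi"
    baseline: float  # ml·min⁻¹
    A1: float  # ml·min⁻¹
    tau1: float  # s
    td: float  # s
    A2: float | None = None
    tau2: float | None = None
    rss: float = float("nan")
    n_iter: int = 0
    converged: bool = True
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.model not in ("mono", "bi"):
            raise ValidationError(f"unknown model: {self.model!r}")
        if self.A1 < 0 or self.tau1 <= 0 or self.td < 0:
            raise ValidationError("require A1 >= 0, tau1 > 0, td >= 0")
        if self.model == "bi":
            if self.A2 is None or self.tau2 is None:
                raise ValidationError("bi model requires A2 and tau2")
            if self.A2 < 0 or self.tau2 <= 0:
                raise ValidationError("require A2 >= 0, tau2 > 0")


@dataclass(frozen=True)
class FitConfig:
    """Fitting controls.

    ``recovery_window`` defaults to 600 s (10 min of recovery); 360 and 480 s
    are the usual alternatives when less recovery was recorded.
    """

    max_iter: int = 1000
    tol: float = 1e-8
    recovery_window: float = 600.0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValidationError("tol must be > 0")
        if self.recovery_window <= 0:
            raise ValidationError("recovery_window must be > 0")


def truncate_recovery(series: BreathSeries, window: float) -> BreathSeries:
    """Retain recovery samples with time ≤ window seconds."""
    if series.phase != "recovery":
        raise ValidationError("truncate_recovery expects a recovery-phase series")
    keep = series.times <= window
    n = int(np.count_nonzero(keep))
    if n < MIN_SAMPLES_MONO:
        raise InsufficientDataError(
            f"only {n} samples within {window:g} s of recovery; need >= "
            f"{MIN_SAMPLES_MONO}"
        )
    if n == len(series):
        return series
    return BreathSeries(
        times=series.times[keep], vo2=series.vo2[keep], phase="recovery"
    )


def _decay(t: np.ndarray, td: float, tau: float) -> np.ndarray:
    # exponent clamped to 0 before the delay: the component holds its full
    # amplitude until the decay starts
    return np.exp(-np.maximum(t - td, 0.0) / tau)


def model_mono(t, params: ExpFitParams):
    """Evaluate the mono-exponential model at time(s) ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    out = params.baseline + params.A1 * _decay(t, params.td, params.tau1)
    return out if out.ndim else float(out)


def model_bi(t, params: ExpFitParams):
    """Evaluate the bi-exponential model at time(s) ``t`` (seconds)."""
    if params.A2 is None or params.tau2 is None:
        raise ValidationError("model_bi requires bi-model parameters")
    t = np.asarray(t, dtype=float)
    out = (
        params.baseline
        + params.A1 * _decay(t, params.td, params.tau1)
        + params.A2 * _decay(t, params.td, params.tau2)
    )
    return out if out.ndim else float(out)


def initial_guess_mono(series: BreathSeries, baseline: float) -> ExpFitParams:
    """Starting values for the mono fit.

    A1 starts at the first sample's excess over baseline; τ1 at the first
    time the excess drops below A1/e (linear interpolation between samples),
    falling back to window/3 when the curve never crosses; td starts at 0.

    Raises
    ------
    DegenerateRecoveryError
        If the series never rises meaningfully above baseline (nothing to fit).
    """
    excess = series.vo2 - baseline
    a1 = float(excess[0])
    if a1 < A_FLOOR or np.all(excess <= 0):
        raise DegenerateRecoveryError(
            "recovery VO2 does not exceed baseline; no off-transient to fit"
        )
    threshold = a1 / np.e
    tau1 = series.duration / 3.0  # fallback: never crosses within the window
    below = np.nonzero(excess < threshold)[0]
    if below.size:
        j = int(below[0])
        if j == 0:
            tau1 = max(float(series.times[0]), TAU_MIN)
        else:
            t0, t1 = series.times[j - 1], series.times[j]
            e0, e1 = excess[j - 1], excess[j]
            # linear interpolation of the crossing time
            tau1 = float(t0 + (e0 - threshold) / (e0 - e1) * (t1 - t0))
    return ExpFitParams(
        model="mono", baseline=baseline, A1=a1, tau1=max(tau1, TAU_MIN), td=0.0
    )


def _run_least_squares(residual, x0, bounds, config: FitConfig):
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        return least_squares(
            residual,
            x0,
            bounds=bounds,
            method="trf",
            xtol=config.tol,
            ftol=config.tol,
            gtol=None,
            max_nfev=config.max_iter,
        )


def fit_recovery(
    series: BreathSeries,
    baseline: float,
    model: str = "mono",
    config: FitConfig | None = None,
) -> ExpFitParams:
    """Fit the off-kinetics model to a (truncated) recovery series.

    The baseline is fixed and excluded from the free parameters. The mono fit
    frees (A1, τ1, td); the bi fit frees (A1, τ1, A2, τ2, td), started from
    the mono solution with the amplitude split 0.8/0.2 and τ2 = 8·τ1.
    Non-convergence within ``max_iter`` evaluations returns the best
    parameters found with ``converged=False`` and a warning, never an
    exception.
    """
    if config is None:
        config = FitConfig()
    if model not in ("mono", "bi"):
        raise ValidationError(f"unknown model: {model!r}")
    min_n = MIN_SAMPLES_MONO if model == "mono" else MIN_SAMPLES_BI
    if len(series) < min_n:
        raise InsufficientDataError(
            f"{model} fit needs >= {min_n} samples, got {len(series)}"
        )

    t = series.times
    y = series.vo2
    window = float(max(series.times[-1], config.recovery_window))
    td_hi = min(TD_MAX, float(t[-1]))

    guess = initial_guess_mono(series, baseline)

    def mono_residual(x):
        a1, tau1, td = x
        return baseline + a1 * _decay(t, td, tau1) - y

    x0 = np.array(
        [guess.A1, min(max(guess.tau1, TAU_MIN), window), min(guess.td, td_hi)]
    )
    lo = np.array([0.0, TAU_MIN, 0.0])
    hi = np.array([np.inf, window, td_hi])
    res = _run_least_squares(mono_residual, x0, (lo, hi), config)
    mono_params = ExpFitParams(
        model="mono",
        baseline=baseline,
        A1=float(res.x[0]),
        tau1=float(res.x[1]),
        td=float(res.x[2]),
        rss=float(2.0 * res.cost),
        n_iter=int(res.nfev),
        converged=bool(res.success),
    )
    if model == "mono":
        return _flag_bounds(mono_params, window)

    # bi fit, warm-started from the mono solution
    def bi_residual(x):
        a1, tau1, a2, tau2, td = x
        return (
            baseline
            + a1 * _decay(t, td, tau1)
            + a2 * _decay(t, td, tau2)
            - y
        )

    tau2_0 = min(8.0 * mono_params.tau1, window)
    x0 = np.array(
        [
            0.8 * mono_params.A1,
            mono_params.tau1,
            0.2 * mono_params.A1,
            tau2_0,
            mono_params.td,
        ]
    )
    lo = np.array([0.0, TAU_MIN, 0.0, TAU_MIN, 0.0])
    hi = np.array([np.inf, window, np.inf, window, td_hi])
    res = _run_least_squares(bi_residual, np.clip(x0, lo, hi), (lo, hi), config)
    a1, tau1, a2, tau2, td = (float(v) for v in res.x)
    if tau1 > tau2:  # relabel so component 1 is the fast one
        a1, tau1, a2, tau2 = a2, tau2, a1, tau1
    params = ExpFitParams(
        model="bi",
        baseline=baseline,
        A1=a1,
        tau1=tau1,
        td=td,
        A2=a2,
        tau2=tau2,
        rss=float(2.0 * res.cost),
        n_iter=int(res.nfev),
        converged=bool(res.success),
    )
    return _flag_bounds(params, window)


def _flag_bounds(params: ExpFitParams, window: float) -> ExpFitParams:
    """Mark fits whose time constant hit the window bound as not converged."""
    taus = [params.tau1] + ([params.tau2] if params.tau2 is not None else [])
    msgs = list(params.warnings)
    converged = params.converged
    if not converged:
        msgs.append("fit did not converge within max_iter")
    for tau in taus:
        if tau >= 0.999 * window:
            converged = False
            msgs.append(
                f"time constant {tau:.1f} s at the window bound; "
                "decay not identifiable"
            )
    return replace(params, converged=converged, warnings=tuple(msgs))


def compute_almet(params: ExpFitParams) -> float:
    """Anaerobic alactic contribution A1·τ1, in liters of O2.

    A1 (ml·min⁻¹) × τ1 (s → min) / 1000 — equal to the analytic integral of
    the fast component from td to infinity.
    """
    return params.A1 * (params.tau1 / 60.0) / 1000.0
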