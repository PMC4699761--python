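# Methods

## The energy-partitioning procedure

The package estimates the energy supplied by the three metabolic systems
during one constant-workload exercise bout followed by seated recovery,
using only whole-body measurements: breath-by-breath oxygen uptake during
exercise and recovery, and blood lactate at rest and after exercise.

**Aerobic.** A_MET is the area under the exercise V̇O₂ curve above rest,
computed with the trapezoid rule on the raw breath-by-breath samples —
no binning, filtering or smoothing is applied first. With times in seconds
and V̇O₂ in ml·min⁻¹, each trapezoid carries a /60 conversion and the result
is reported in liters. The baseline is subtracted as rate × duration rather
than sample-by-sample; the two are identical for a constant rate under the
trapezoid rule, and the rate form stays well defined for the fixed per-kg
convention. A negative net area (baseline above the exercise V̇O₂) is
returned with a warning, never clamped: surfacing a data problem beats
hiding it.

**Anaerobic alactic.** AL_MET is the fast-component area of the
post-exercise V̇O₂ off-kinetics, A₁·τ₁, which equals the analytic integral
of A₁·e^(−(t−td)/τ₁) from td to infinity. The model asymptote (the
baseline) is fixed to the same resting value used for the aerobic phase and
excluded from the free parameters; consequently baseline mode `ignore`
cannot be combined with the alactic system and is rejected up front. The
choice between the mono- and bi-exponential model is a user flag — mono
after moderate-intensity exercise, bi after severe — never auto-detected;
no model-selection criterion (AIC, F-test) is applied, and the slow
component of a bi fit contributes no energy (only A₁·τ₁ counts).

**Anaerobic lactic.** LA_MET = Δ[La⁻] × equivalent × body mass, with
Δ[La⁻] = peak − rest in mmol·l⁻¹ and a default equivalent of 3 ml O₂·kg⁻¹
per mmol·l⁻¹ (5.3 is another value used in the literature; the constant is
a parameter). A negative delta is reported as computed, with a warning.
Lactate kinetics (production/clearance balance) are not modelled; the
accumulation equivalent is a recognized approximation of the method itself.

**Assembly.** Liters of O₂ are the canonical unit; kilojoules and
kilocalories are always derived via the fixed equivalents 20.9 kJ·L⁻¹ and
5 kcal·L⁻¹ and never stored separately, which removes any possibility of
the three unit rows drifting apart through rounding. Percentages are
emitted only for positive totals. Reports round to 1 decimal for display;
JSON keeps full precision.

## Fitting: parameterization, initialization, bounds

The least-squares problem is solved with scipy's trust-region reflective
damped least-squares solver (`least_squares`, method `trf`), chosen because
the fit is bounded: amplitudes ≥ 0, time constants in (1 s, window], time
delay in [0, 60 s]. The bounds prevent sign-flipped "fast components",
delta-like spikes, and component swapping; a delay beyond 60 s has no
physiological meaning for off-kinetics. Any damped least-squares minimizer
meeting the tolerances would do; results are deterministic for identical
inputs and configuration.

Mono initialization: A₁ starts at the first sample's excess over baseline
(floor 1 ml·min⁻¹ — below that there is no transient and the fit is refused
as degenerate); td starts at 0; τ₁ starts at the time where the excess first
crosses A₁/e, located by linear interpolation between samples, falling back
to window/3 if the curve never crosses.

Bi initialization is warm-started from the mono solution: amplitudes split
0.8/0.2, τ₂ = 8·τ₁ (clipped to the window), td carried over. The split and
the factor 8 reflect the typical dominance of the fast component and the
order-of-magnitude separation between phosphagen and slow-recovery time
constants; the exact values only seed the optimizer. After the fit the two
components are relabelled so that τ₁ < τ₂ always names the fast one.

Convergence uses scipy's relative tolerances (`xtol = ftol = tol`,
default 1e-8) with a cap of 1000 function evaluations. A fit whose time
constant lands at the window bound (within 0.1%) is flagged not converged:
a decay slower than the observation window is unidentifiable from that
window. Non-convergence returns the best parameters found plus a warning
rather than raising — the caller sees both the numbers and their status.

Recovery fits require at least 5 samples (mono) or 7 (bi) inside the
window, and the recovery window defaults to 600 s (6- and 8-min windows are
the standard alternatives).

## Input conventions

Series are two-column delimited text (time, V̇O₂). Numerals use the point
as decimal separator and optionally the comma as thousands separator —
the source sentence describing this dialect is garbled, and it is
interpreted here as comma = thousands, point = decimal, consistent with the
"English decimal separator" requirement stated alongside it. Because the
comma is a numeral character, it is not accepted as a field delimiter (tab,
semicolon or whitespace runs are). Times may be seconds or `hh:mm:ss`; a
cumulative clock is normalized so every series starts at 0. A single header
line is skipped when both of its fields fail numeric parsing. V̇O₂ outside
[0, 10 000] ml·min⁻¹ is rejected as a probable unit mistake (e.g. data in
L·min⁻¹).

## Synthetic data

The generator emulates what a metabolic cart produces: one sample per
breath at a mean interval of 2 s with ±30% uniform timing jitter, and
multiplicative Gaussian noise (default sd 5% of the local signal, floored
at 0) approximating breath-to-breath variability. Exercise V̇O₂ follows
baseline + amplitude·(1 − e^(−t/τ_on)) with defaults of 300 ml·min⁻¹
baseline, 1500 ml·min⁻¹ plateau, τ_on = 30 s and 10 min duration — a
moderate-to-heavy constant-load bout for a trained adult; recovery defaults
to a mono decay with A₁ = 1500 ml·min⁻¹, τ₁ = 45 s, td = 5 s over 10 min.
The generator returns the exact analytic ground truth (net exercise volume;
true kinetic parameters) alongside each series, and identical seeds yield
identical output.

What it deliberately omits: the cardiodynamic phase at exercise onset, the
slow drift of the V̇O₂ slow component during heavy exercise, heavy-tailed
breath noise, and any lactate kinetics. Passing tests therefore show that
the estimators recover first-order kinetics accurately under realistic
sampling and noise — not that real recoveries are first-order.

## Problem sizes and numerical checks

The test suite and the reproduction script use 10-min series at 1-s (clean
checks) or ~2-s jittered (noisy checks) sampling — about 300–600 breaths,
matching a real 10-min recording — and 200 replicates for the noisy-bias
check. Clean mono fits recover parameters to ~1e-12 relative error (the
suite asserts 1e-6), clean bi fits with τ₂/τ₁ = 10 to better than 1e-3, and
the median fast-component energy bias under 5% multiplicative noise is
about 1.5%. AL_MET from 6-, 8- and 10-min windows agrees to well under 1%
on clean data with τ₁ ≤ 60 s, the deterministic analogue of the empirical
observation that the recovery duration does not change the estimate.

## Known limitations

- The off-kinetics share a single time delay across both components, as the
  governing model prints it; some laboratories fit separate delays.
- The baseline fixed in the recovery fit is the pre-exercise rest value,
  not an end-recovery plateau; if V̇O₂ has not returned to pre-exercise
  rest within the window, the fast-component amplitude absorbs the gap.
- No confidence intervals on fitted parameters; the method reports point
  estimates and residual diagnostics only.
- Group statistics across subjects (means, reliability coefficients) are
  out of scope; the tool computes one profile per test.
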