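# Methods

## Model

The analysis treats a muscle region as a lumped first-order RC circuit.
Oxygen partial pressure maps to voltage, oxygen flux to current. Arterial
blood is an ideal constant-pressure source *P*ₐ (mmHg); a delivery
resistance *R*d connects it to the interstitial node at pressure *P*ᵢ; a
metabolic resistance *R*m drains the node to zero potential (oxygen
converted to water carries no partial pressure); a capacitance *C*
(nL O₂ cm⁻³ mmHg⁻¹) stores oxygen at the node. Resistances are in
mmHg/(nL O₂ cm⁻³ s⁻¹), so any R·C product is a time in seconds.

Consequences used throughout:

- steady state (divider): *P*ᵢ = *P*ₐ·*R*m/(*R*d+*R*m); Kirchhoff balance
  (*P*ₐ−*P*ᵢ)/*R*d = *P*ᵢ/*R*m;
- transient: exponential relaxation with τ = *C*·*R*d*R*m/(*R*d+*R*m)
  (Thévenin resistance seen by the capacitor), equivalently
  τ = *C·R*d·*P*ᵢ/*P*ₐ — the form measurable from one steady state;
- two metabolic states (rest *R*r, work *R*w < *R*r) with instantaneous
  switching: cellular respiration adjusts in ~1 s, two orders faster than
  the PO₂ transients it drives, so *R*m is piecewise constant. An optional
  first-order activation lag exists nowhere in this package: the strict
  two-state model is the implemented scope;
- the asymmetry prediction τr/τw = *P*r/*P*w, since both time constants
  share *C·R*d.

The nonlinear variant replaces the consumption resistor by a workload's
Hill curve *V*(*P*) = *V*max·*P*ⁿ/(*P*₅₀ⁿ+*P*ⁿ) and solves
*C*·d*P*ᵢ/dt = (*P*ₐ−*P*ᵢ)/*R*d − *V*(*P*ᵢ). Steady states are then
load-line/curve intersections; the constant resistor *R*m = *P*ᵢ\*/*V*\*
defined at the intersection reproduces the same operating point in the
linear circuit (resistor-replacement equivalence, tested to 1e-9 mmHg).

## Units and calibration

Absolute resistances are not measurable from PO₂ data alone, so all
computations run in relative units with the young-cohort delivery
resistance as the reference, *R*d = 1. Absolute fluxes are reported only
as ratios unless the user supplies a solubility-based capacitance.
*C* is likewise never observed directly; what the data pin down is the
product *C·R*d = τ·*P*ₐ/*P*ᵢ per state. For the packaged young cohort the
rest state gives *C·R*d = 15.4·91.9/66.7 ≈ 21.22 s and the work state
≈ 19.46 s; the ~8% gap (19% in the old cohort, computed on rounded table
ratios) is the model-consistency diagnostic exposed as
`tau_consistency`.

## Per-state effective capacitance (design decision)

A single shared *C* cannot reproduce both measured time constants of a
cohort — that is exactly what the consistency gap says. Summary inversion
(`invert_summary`) therefore offers two conventions:

- `"per-state"` (default): each state's effective capacitance is set from
  its own measured τ, so simulated traces carry exactly the measured
  onset and offset kinetics. This is the right generator for emulating
  recordings and for closed-loop validation of the fitter (measured traces
  have the measured τ's, whatever single-C theory says).
- `"rest"`: strict single-capacitance circuit calibrated on the resting
  baseline; the simulated work transient then shows τ = *C·R*d·*P*w/*P*ₐ
  and the whole consistency gap lands in τw. This mode is used to verify
  the τr/τw = *P*r/*P*w closure, which holds only for a true single-C
  circuit.

`simulate_protocol` always requires shared *P*ₐ and *R*d across states and
requires shared *C* unless `allow_state_capacitance=True`.

## Parameters and defaults

| parameter | units | default | rationale |
|---|---|---|---|
| protocol | s | 10 rest / 90 work / 150 recovery | the standard stimulation protocol behind the packaged cohorts |
| sampling interval | s | 0.1 | ≥ 90 samples per shortest reference time constant |
| RK4 step | s | sampling/10 | smooth scalar ODE; fixed step for bit-reproducibility across platforms |
| measurement noise SD | mmHg | 1.0 | gives transient-fit precision comparable to the reference CI95 at the published profile counts |
| reference *R*d | R-units | 1 (young) | only ratios are observable |

Packaged inputs (`oxcircuit/data/*.yaml`): young cohort *P*ₐ = 91.9 ± 5.4
(n = 11 animals), *P*r = 66.7 ± 2.5, *P*w = 42.5 ± 2.6, τw = 9.0 ± 0.7,
τr = 15.4 ± 0.7 (n = 117 profiles); old cohort 81.3 ± 5.1 (n = 12),
60.2 ± 2.2, 28.3 ± 2.8, 15.9 ± 0.6, 41.4 ± 1.4 (n = 139). Values are
means ± CI95 half-widths.

## Numerical choices

- **Operating point**: Brent's method bracketed on [0, *P*ₐ], xtol 1e-12
  mmHg. A root always exists (delivery ≥ 0 = consumption at *P*ᵢ = 0,
  delivery = 0 ≤ consumption at *P*ᵢ = *P*ₐ) and is unique by opposing
  monotonicity; a zero-consumption curve pins the node at *P*ₐ.
- **Exponential fit**: Levenberg–Marquardt on
  *P*(t) = *P*∞ + (*P*₀−*P*∞)e^(−t/τ); initialization *P*∞⁰ = mean of the
  final 20% of the segment, *P*₀⁰ = first sample, τ⁰ from log-linear
  regression of |*P*−*P*∞⁰| over the first 60% (fallback: span/3);
  convergence at relative parameter change < 1e-10 within 500 residual
  evaluations; uniform weights (no heteroscedastic noise model is
  assumed). Flat segments (variance < 1e-12) are rejected as degenerate;
  fitted τ ≤ 0 is rejected as non-exponential. In ensemble studies, fits
  whose τ exceeds the segment span violate the estimator's validity
  precondition (segment must span ≥ 1 time constant) and are excluded.
- **Two-state extraction**: the baseline *P*r is the phase mean (the
  baseline is assumed at equilibrium), *P*w and τw come from the
  work-onset fit, τr from the recovery fit whose asymptote is freely
  estimated and reported as a diagnostic against *P*r rather than pinned
  to it.
- **ODC differentiation**: central differences on raw samples (one-sided
  at the ends); optional odd-window moving-average smoothing, off by
  default; the initial-slope VO₂ uses the first 5 samples' regression
  slope (configurable). No correction for residual intravascular oxygen
  is applied.
- **Identity tests** use relative tolerance 1e-12 with parameters drawn
  from physiological ranges (resistances 0.05–20, *P*ₐ 20–150 mmHg); the
  closed forms are evaluated directly, never via the ODE path.
- **Display rounding** for tables: one decimal for ratios ≥ 1, two below
  1. Comparisons against published table entries use a ±0.75-last-digit
  band because printed rounding is not always the nearest-decimal value
  of the unrounded quantity (e.g. 5.343 appears as 5.4).

## Synthetic cohorts: what is and is not emulated

`sample_cohort` draws per-animal parameter sets from independent normal
distributions with SD back-converted from the CI95 half-widths
(SD = CI95·√n/1.96, n = animals for *P*ₐ, profiles for tissue values). No
between-parameter covariance is modelled (none is published); correlated
draws would require a user-supplied covariance and are out of scope.
Because tissue summaries aggregate profiles, not animals, the variance
layout is ambiguous; both a `two_level` mode (default; equal
between/within-animal variance split, animals drawn at SD/√2) and a
`flat` mode (all variance between animals) are provided. Draws violating
*P*ₐ > *P*r > *P*w > 0 or τ > 0 are rejected and redrawn; note that this
truncation necessarily shifts the realized means and shrinks spreads when
the specified variability is large relative to the gaps (a few percent at
the packaged cohorts' variability in flat mode), so ensemble validation
compares extracted estimates against the *sampled* cohort's own truth,
not against the nominal means.

`generate_trace` emulates: the rest–work–recovery protocol, piecewise-
exponential transitions with the measured per-state kinetics, and i.i.d.
Gaussian measurement noise. It does not emulate: phosphorescence photon
statistics or probe oxygen consumption, baseline drift, arterial PO₂
fluctuation during exercise, movement artifacts, or spatial heterogeneity
(this is a lumped model; no diffusion geometry). Passing closed-loop
tests therefore demonstrates estimator correctness under the stated noise
model, not robustness to every artifact of real recordings.

## Validation problem sizes

Algebraic identities: 10⁴ random circuits. Operating-point solver vs
bisection oracle: 10³ random problems at 1e-9 mmHg. Noisy time-constant
recovery: 500 replicates of the 90-s work-onset segment at 1 mmHg noise
(ensemble mean within 2%). Load-line recovery: 1000 replicates at 5% flux
noise. Full pipeline (sample → simulate → extract → ratios): 300 animals
at the young cohort's variability, ensemble ratios within 5% of the
sampled truth. These sizes give comfortable statistical margins while
keeping the full suite in tens of seconds on a laptop.

## Known limitations

- The source is ideal: no hemoglobin dissociation nonlinearity, no
  arterial PO₂ dependence on work rate.
- Strictly monoexponential per state: no multi-exponential or delayed-
  onset kinetics, so data with a genuine cardiodynamic-style delay will
  bias τ estimates.
- Two discrete metabolic states at moderate intensity only; the Hill-curve
  integrator generalizes the consumption branch but workload-specific Hill
  parameters are user-supplied, not fitted from published figures.
- The old cohort's 19% consistency gap means single-capacitance
  predictions of work-onset kinetics are systematically fast; per-state
  effective capacitance reproduces measurements but is descriptive, not
  mechanistic.
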