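# Methods

## Model and assumptions

The package implements an SIR model on population fractions with three
departures from the textbook system: a vertical transmission route (a
fraction q = 1 − p of offspring of infected parents is born infected), a
vaccination term with *temporary* immunity (susceptibles vaccinated at
t − ω re-enter the susceptible class at t, discounted by the survival
probability e^{−bω}), and a Crowley–Martin incidence
βSI / (1 + α₁S + α₂I + α₁α₂SI) that saturates in both classes. Birth and
death rates of all classes are assumed equal (a single constant b), which
keeps the total population constant; all state variables are fractions of
that total. Environmental fluctuation enters the transmission coefficient
as white noise, β dt → β dt + σ dB, giving a diffusion term ±σSI/f dB
driven by one shared Brownian motion (negative on S, positive on I), so
S + I + R = 1 carries no noise.

The reduced stochastic system tracks only (S, I); R = 1 − S − I is
bookkeeping. Some of the built-in stochastic scenarios start at
(S(0), I(0)) = (0.7, 0.4), i.e. off the unit simplex; the reduced system
is well defined there and the implied R(0) = −0.1 is transient
bookkeeping, not a population. Starts inside the invariant region
S + I ≤ b/(b + m(1 − e^{−bω})) remain there (deterministically exactly;
stochastically up to discretization excursions).

## Parameters

| name | meaning | units | typical value here |
|------|---------|-------|--------------------|
| β | transmission coefficient | 1/time | 0.4–0.8 |
| b | birth = death rate | 1/time | 0.3 |
| p | susceptible fraction of infected parents' offspring | — | 0.1–0.5 |
| m | vaccination proportion of susceptibles | — | 0.2–0.9 |
| α₁, α₂ | incidence inhibition constants | — | 0.6, 0.1 |
| γ | recovery rate | 1/time | 0.2 |
| ω | vaccine validity period (delay) | time | 1–5 |
| σ | noise intensity on β | 1/√time | 0.1–0.9 |

ω = 0 is allowed (the waning term degenerates, e^{−bω} = 1) so bilinear
no-waning limits are testable. Validity: β, b > 0; p, m ∈ (0, 1); the
rest nonnegative.

## Thresholds and regime classification

All closed forms (R₀¹, R₀², R₀ˢ, the region cap, both equilibria, λ_I,
I\*) are evaluated in double precision and rounded only for display. Two
design points were genuinely open:

* **The symbol in the endemic I_e.** The endemic equilibrium's
  I_e = b/(b + γ)(1 − 1/R₀¹) is implemented with the recovery rate γ in
  the denominator; with that reading the triple sums to one and zeroes
  the steady-state right-hand side exactly (verified symbolically and
  asserted to 1e−12 in the tests).
* **Overlapping extinction conditions.** The large-noise condition (a)
  (σ² > β²/(2(pb+γ))) and the sub-threshold condition (b) (R₀ˢ < 1 with
  the noise cap σ² ≤ β(b + α₁b + m(1 − e^{−bω}))/b) are not mutually
  exclusive. Both decay bounds are exposed (`lambda_a`, `lambda_b`),
  `lambda_I` is the tighter (most negative) of the two — both hold
  almost surely, so the minimum is the sharpest valid bound — and the
  regime label gives condition (b) precedence (`extinct_b` before
  `extinct_a`), matching how the simulation scenarios are classified.
  This choice is lossless: nothing is discarded.
* **A noise-intensity inconsistency in the persistent scenario.** For
  β = 0.8 with the remaining standard values, σ = 0.5 gives
  R₀ˢ = 1.1757, while the printed persistent-regime threshold 1.2712 is
  reproduced by σ = 0.2 (the intensity the weak-noise runs use). The
  registry keeps `sto-fig3c` at the stated σ = 0.5 (with a note in its
  threshold report) and adds `sto-persistent` with σ = 0.2, which is the
  parameter set all persistence diagnostics use.

## Deterministic integration

Classical RK4 with fixed step (default Δt = 0.1, matching the stochastic
grid) and a history buffer for the delayed term. The delayed value
S(t − ω) at each stage is obtained by **cubic Hermite dense output**
(node values plus stored node derivatives) into the committed grid — a
linear lookup would cap the integrator at second order; with Hermite
interpolation step-halving shrinks endpoint errors by ≳16×, and the test
asserts ≥8× away from the delay-activation kink at t = ω. Queries before
t = 0 go to the history function, by default the constant S(θ) ≡ S(0);
a tabulated (piecewise-linear) history may be supplied. R(0) defaults to
1 − S(0) − I(0). The default horizon is t_end = 100, a declared
convention (long enough for every built-in scenario to reach its
asymptotic regime at these rates).

## Stochastic integration

The Euler–Maruyama step uses the drift of the reduced system and the
shared noise ±g√Δt ξ with g = σSI/f; the Milstein step adds the
correction ∓0.5σ²(SI/f)(ξ² − 1)Δt (minus on S, plus on I), implemented
**exactly in that printed form**. Note this is a simplified correction:
the true Milstein term involves the state derivative of the diffusion
coefficient, so the scheme as printed retains strong order 1/2, the same
as Euler–Maruyama. Consequences measured and documented:

* the pathwise gap between the two schemes is an accumulated mean-zero
  term of size O(√Δt): halving Δt shrinks max|ΔI| by ≈√2 (measured
  ratios 1.38 and 1.56 across Δt = 0.1 → 0.05 → 0.025 with a shared
  refined Brownian path), not by 2;
* the correction is quadratic in ξ with positive coefficient on I, which
  at moderate σ actually shields I from undershooting zero where EM
  would clamp.

The delay index is k − round(ω/Δt); configurations where ω/Δt is not
integral (beyond 1e−8) are rejected rather than interpolated, keeping
the stepping exactly the printed scheme. Negative undershoots follow the
`positivity_policy`: `truncate` (default) clamps the component at zero
and counts the event — a clamped I stays zero thereafter since drift and
diffusion are proportional to I, consistent with extinction semantics —
while `error` aborts with the step index. Path i of an ensemble draws
from an independent substream seeded by SeedSequence(entropy=seed,
spawn_key=(i,)), a counter-based construction that is reproducible
across platforms; ensembles average 50 realizations pointwise by
default.

## Finite-horizon diagnostics

The theory's claims are asymptotic; the diagnostics make them measurable
on T = 100:

* **Extinction**: per-path least-squares slope of ln(max(I, 1e−300))
  over the tail window (default last 50% of the horizon), compared with
  λ_I + 0.05; the check passes when ≥90% of paths comply (the bound
  holds almost surely but finite paths fluctuate). The report also
  carries the ensemble median slope.
* **Persistence**: the tail average of the running time average
  ⟨I⟩(t) = (1/t)∫₀ᵗ I ds (trapezoid, exact on affine signals) of the
  ensemble mean, compared with (1 − 0.1)·I\*.

Calibration caveat, measured not assumed: for the large-noise extinction
scenario (β = 0.4, σ = 0.9) the bound λ_I = −0.2512 is nearly *tight* —
the true asymptotic slope near the disease-free state is ≈ −0.2532 — so
with path-slope standard deviation ≈ 0.06 (ln I noise volatility
σS/f ≈ 0.51 over a length-50 window) only ~75–85% of paths fall within
the 0.05 tolerance and the 90% majority vote fails robustly; the median
slope respects the bound comfortably. The same near-tightness holds for
the σ = 0.9, β = 0.8 scenario (bound −0.0276 vs true ≈ −0.0276). The
tolerances (0.05/time slope, 10% relative persistence, 90% majority) are
engineering defaults, all configurable.

## What the scenarios do and do not emulate

The built-in scenarios are the model's own parameter grids (transmission
× delay for the deterministic panels; transmission × noise, delay
sweeps, p/m sweeps and immunity-level runs for the stochastic ones),
with the initial values stated above. They are synthetic model runs, not
data: passing tests demonstrates internal consistency of thresholds,
schemes and theorems at these parameter magnitudes — not fit to any real
epidemic. Sweep values for the vaccination-proportion and birth-rate
panels (m ∈ {0.2, 0.4, 0.8}; b ∈ {0.2, 0.3, 0.4}) are package defaults,
marked as such in the scenario notes. The immunity level
V(t) = ∫₀ᵗ [mS − mS(s − ω)e^{−bω}] ds is advanced by trapezoidal
quadrature with V(0) = 0.

## Problem sizes

Default runs are 50 paths × 1000 steps (Δt = 0.1, T = 100) per
stochastic scenario — under a second each on one core — and single RK4
trajectories of 1000 steps for the deterministic panels. The scheme
comparison uses single paths at Δt ∈ {0.1, 0.05, 0.025}.

## Known limitations

* No adaptive stepping, stiff solvers, event detection, or exact SDE
  simulation; the stochastic schemes are exactly the printed
  discretizations (strong order 1/2).
* No inference: parameters are inputs, never fitted to incidence data.
* The regime diagnostics are engineering checks of asymptotic
  statements, not formal statistical tests; no confidence intervals are
  attached to the measured slopes.
* The unequal-rates variant of the model (distinct birth/death rates per
  class) is out of scope; only the equal-rates reduction is implemented.
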