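# Methods

## Model

Three populations, all in units of 10⁶ (one mm³ of tumor ≈ 10⁶ cells):
uninfected tumor cells `x`, infected tumor cells `y`, free virions `v`.

```
dx/dt = r x (1 − (x+y)/K) − β x v − ρ x y
dy/dt = Σᵢ βᵢ x(t−τᵢ) v(t−τᵢ) − δ y
dv/dt = b δ y − γ v − β x v
```

The uninfected pool grows logistically (rate `r`, capacity `K`) and is
lost to free-virus infection (`β x v`) and to syncytium-forming fusion
with infected cells (`ρ x y`). Infection takes effect only after the
viral lytic cycle completes; its stages are represented by a set of
discrete delays, each channel `(βᵢ, τᵢ)` feeding the infected pool with
the encounter rate evaluated `τᵢ` days ago. One channel may be
instantaneous (`τ = 0`). The total rate constant `β = Σᵢ βᵢ` (including
any instantaneous term) is what appears in the `x` and `v` equations —
mass lost from the susceptible pool and virions absorbed into cells are
not delayed, only the appearance of productively infected cells is.
Infected cells lyse at rate `δ`, each releasing `b` virions (burst
size); free virus is cleared at rate `γ`.

Time is measured in days. This convention affects labels only; none of
the sources state a unit and all rate constants are used as printed.

### Equilibria and threshold

- `E0 = (0,0,0)` — tumor eradicated (always unstable here: with no
  virus the tumor regrows).
- `E1 = (K,0,0)` — therapy failure, tumor at carrying capacity.
- `E* = (x*, y*, v*)` — coexistence; from the steady-state balances
  `x* = γ/(β(b−1))`, `y* = β x* v*/δ`, and `v*` from the logistic
  balance. Positive exactly when the basic reproduction number
  `R0 = βKb/(βK+γ)` exceeds 1.

`equilibria` enforces a residual check (RHS max-norm ≤ 1e−9·K) on every
returned point; delays are irrelevant at steady state. Burst size is
treated as the free calibration parameter: scenarios specify `R0` and
`b = R0(βK+γ)/(βK)` is solved by `burst_size_for_r0`.

## DDE integration (method of steps)

Delayed terms reach back at most `τ_max`, so any step shorter than the
smallest positive delay only consults already-computed solution. The
integrator runs Dormand–Prince (scipy `RK45`) with `max_step` capped at
the smallest positive delay, collecting each accepted step's
dense-output polynomial; delayed states are interpolated from that
record, and the constant history `φ(θ) = (x₀, y₀, v₀)` on `[−τ_max, 0]`
serves for `t ≤ 0`. Step endpoints are forced at the first-generation
derivative breakpoints `τ₁ < … < τₙ` by splitting the integration
there; deeper-generation breakpoints (sums of delays) are left to the
adaptive error control, which is adequate at the smoothness the
analyses need.

Choices that matter:

- **Constant history.** The scenarios specify only point initial
  conditions; the constant-history reading is the standard one. It
  changes transients, never equilibria or stability.
- **Tolerances.** Defaults `rel_tol = 1e−8`, `abs_tol = 1e−10`
  (config-overridable). Halving both moves the 300-day terminal state
  of the damped single-delay scenario by ~4e−8.
- **No negativity clamping.** Excursions below `−abs_tol` abort with a
  diagnostic rather than being corrected: clamping would mask solver
  misconfiguration. State norms above `1e6·K` abort as blow-up.
- Long-horizon runs (2000 days) of the multi-delay presets take a few
  seconds: the 0.2-day smallest delay caps steps at 10⁴ for the run.

## Stability analysis

**At `E1`, delay-free.** The Jacobian factors; eigenvalues are `−r` and
the roots of a quadratic with discriminant
`Δ = (γ+βK−δ)² + 4βKbδ > 0`. The larger quadratic root has the sign of
`R0 − 1`, so the threshold eigenvalue crosses zero exactly at `R0 = 1`
(verified by bisection on `b` in the tests).

**At `E1`, any delays.** A purely imaginary characteristic root `iω`
must satisfy `ω⁴ + a1 ω² + a2(ω) + a3 = 0` with
`a1 = (γ+βK)² + δ² > 0`,
`a2(ω) = 2(bKδ)² Σ_{i<j} βᵢβⱼ(1 − cos ω(τᵢ−τⱼ)) ≥ 0`, and
`a3 = δ²(γ+βK)²(1 − R0²)`. For `R0 < 1` all three are positive, so no
crossing exists at any delay; `dfe_delay_robustness` records `a1`,
`a3` and the grid minimum of `a2` and issues the certificate iff
`R0 < 1`. The quantifier over `ω` is realized as a dense grid check
(default 10⁴ points on `(0, ω_max]`), an explicitly *sufficient*
semantics recorded in the certificate.

**At `E*`.** The characteristic equation is

```
λ³ + A λ² + B̃ λ + C + Σᵢ βᵢ e^(−λτᵢ) (D λ + E) = 0.
```

The coefficients are extracted from the determinant of the
linearization rather than transcribed: the delayed sum enters the
Jacobian affinely through a scalar `S`, so the delay-free cubic is the
characteristic polynomial of `J(S=0)` (via `numpy.poly`) and `(D, E)`
is the affine increment evaluated at `λ = 0, 1` — an exact extraction.
Published closed forms for `A`, `C`, `D`, `E` are reproduced to 1e−9
relative in the tests; the printed form of `B̃` is typographically
ambiguous in the source material, so it is validated only against the
determinant oracle (agreement of the two characteristic-function
routes at random complex `λ` to 1e−9).

With all delays zero the cubic becomes
`λ³ + A λ² + (B̃+βD) λ + (C+βE)` and is tested by Routh–Hurwitz
(`H2 = b1·b2 − b3`; any quantity within 1e−9 of zero yields a
"marginal" verdict rather than a sign call). For arbitrary delays,
positivity of `K1` and of the ω-dependent `K2(ω)`, `K3(ω)` over the
grid — which for a single positive delay collapse to the constants
`K1 = A² − 2(B̃+β₀D)`, `K2 = (B̃+β₀D)² − 2A(C+β₀E) − (β₁D)²`,
`K3 = (C+β₀E)² − (β₁E)²` — certifies that no root can reach the
imaginary axis, hence delay-independent local stability.

## Hopf bifurcation (single positive delay)

A crossing `λ = iω` requires `u = ω²` to solve
`h(u) = u³ + K1 u² + K2 u + K3 = 0`; `K3 < 0` guarantees a positive
root. `ω₀` is the largest positive root (all roots are reported). The
real/imaginary parts of the characteristic equation form a linear
system in `cos ωτ` and `sin ωτ`, solved jointly so the angle
`θ = atan2(sin, cos) ∈ [0, 2π)` carries no quadrant ambiguity
(`cos² + sin² = 1` is verified to 1e−6); the crossing delays are
`τ = (θ + 2πj)/ω₀`, `j = 0, 1, …`, and `τ*` is the smallest positive
one. Enumerating from `j = 0` (principal branch) is what reproduces
the reference value `τ* ≈ 8.836`.

Transversality — the root pair actually moving into the right
half-plane as `τ` grows through `τ*` — is decided by `sign h′(ω₀²)`
and *always* cross-validated by Newton continuation of the exact
transcendental characteristic root from `iω₀` to `τ* ± 0.5`;
disagreement aborts. On the reference single-delay scenario the
measured crossing speed is `dReλ/dτ ≈ 6e−3`/day.

### Delay classification

`classify_delay` integrates from a deterministic 1% multiplicative
perturbation of `E*` (constant history, default horizon 3000 days) and
grades the ladder of `x`-peak amplitudes after discarding the first 20%
of the horizon. Amplitudes are peak **prominences** (height above the
surrounding baseline, scipy `find_peaks`): the perturbation also
excites a slowly-relaxing real mode (decay time of order 10³–10⁴ days
near the reference calibration), and prominences are insensitive to
that drifting offset where "peak minus x*" is not. Rules: monotone
decay by ≥1% per cycle → `damped` (likewise when the oscillation has
died out entirely within the discarded transient, judged on the
full-horizon ladder); last four amplitudes within 5% → `sustained`;
otherwise `growing-then-bounded`; fewer than four usable peaks anywhere
→ `inconclusive`. With a ~40-day cycle the 1%-per-cycle rule places the
damped/sustained boundary a fraction of a day below `τ*`, consistent
with an exactly-at-`τ*` flip at the resolution of any finite-horizon
criterion.

## Lyapunov diagnostics

For `R0 < 1` the functional
`V(t) = b y(t) + v(t) + b Σᵢ βᵢ ∫_{t−τᵢ}^{t} x v ds`
is nonincreasing along solutions; `lyapunov_value` evaluates it on the
dense trajectory (adaptive quadrature, tolerance 1e−10) with a numeric
central-difference derivative (step 1e−3 days), and
`lyapunov_monotone_check` verifies nonincrease on a grid up to
`1e−8·max V` of solver/quadrature noise. The algebraic decrease bound
`βKb(1 − 1/R0)·v` is exposed separately (`lyapunov_decrease_bound`) so
the inequality itself can be cross-checked. Applied at `R0 ≥ 1` the
check reports "not applicable" — the theory makes no claim there.
`V` needs the memory window `[t−τ_max, t]`, so it is defined for
`t ≥ 0` on a trajectory with constant history.

Scenario summaries call a run converged when the terminal state is
within `1e−3·K` (max-norm) of a known equilibrium — scale-aware, in the
10⁶-cell unit convention — and call it a cycle when late-window
oscillation amplitude exceeds that same scale.

## Synthetic fixtures

`random_fixture` draws seeded parameter sets for property tests: rates
jittered log-uniformly ±20% around the reference calibration, 1–n
positive delays uniform on (0.1, 5) days plus an instantaneous channel
with rates log-uniform on 10⁻⁵–10⁻³·⁵, and `b` solved for a target `R0`
drawn from a requested range — so existence/stability properties can be
exercised on both sides of the threshold deterministically. The
fixtures emulate the *structure* of the study conditions (multi-channel
delayed transmission, realistic rate magnitudes), not real tumor data:
no measurement noise, no parameter correlations, no immune response or
spatial effects. Tests passing on them demonstrate internal
mathematical consistency of the implementation, not clinical validity
of the model.

## Known limitations

- The Hopf machinery is restricted to exactly one positive delay (plus
  an optional instantaneous channel); multi-delay critical surfaces are
  out of scope, as is the direction/stability of the bifurcating
  periodic orbit (no center-manifold computation).
- Delays are constant and discrete; no distributed or state-dependent
  lags.
- Grid-based certificates are sufficient checks, not proofs: a
  sign change between grid points would be missed (mitigated by the
  10⁴-point default density and the smoothness of the trigonometric
  cross-terms).
- The classification of dynamics near `τ*` is horizon-limited; within
  a fraction of a day of `τ*` any trajectory-based criterion blurs the
  boundary.
- Global stability of `E1` is certified trajectory-wise (Lyapunov
  nonincrease on computed runs), not proven over the whole phase space.
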