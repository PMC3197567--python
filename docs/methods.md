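# Methods

## Model and assumptions

Three species react and diffuse in a tissue slab: a free chemical *a*
(concentration `A`), its binding partner *b* (`B`) and their complex *c*
(`C`). The complex forms reversibly (`a + b ⇌ c`, rates `k₊₁`, `k₋₁`) and
is additionally cleaved inside the tissue at rate `k₋₂`, releasing *a*
without returning *b*; *a* and *b* are removed at first-order rates `α₁`,
`α₂`. Geometry is a 1-D slab `−1 ≤ x ≤ 1` assumed symmetric about the
midplane, so only `0 ≤ x ≤ 1` is computed, with zero flux at `x = 0`.
All three boundary concentrations are held fixed — appropriate for a
chemical supplied by well-mixed serum/synovial fluid or a sustained
infusion — and nondimensionalised to 1. Only steady states are analysed;
the solver integrates the time-dependent equations purely as a relaxation
method. No advection, no 2-D/3-D geometry, no time-varying boundary data.

Scaling: space by the half-width `L`, time by the complex diffusion time
`L²/D_C`, concentrations by their boundary values. The nine groups are

| group | meaning | appears as |
|---|---|---|
| `λ₁ = L²k₊₁A*B*/(C*D_C)` | complex formation | the perturbation parameter |
| `λ₂ = L²(k₋₁+k₋₂)/D_C` | total complex breakdown | source of *a*, sink of *c* |
| `λ₃ = α₁L²/D_C` | removal of *a* | the targeting antagonist |
| `λ₄ = α₂L²/D_C` | removal of *b* | controls partner persistence |
| `λ₅ = L²k₋₁C*/(B*D_C)` | dissociation (for the *b* equation) | source of *b* |
| `δ_A, δ_B` | diffusivity ratios `D/D_C` | — |
| `μ_A = C*/A*, μ_B = C*/B*` | boundary concentration ratios | coupling strengths |

`μ_B = 0` is accepted with a warning (`ZeroCouplingWarning`): it
decouples complex formation from the *b* equation and appears in a
published counterexample used here as a regression fixture for the
expansion-validity warning; all other ratio parameters must be strictly
positive, and zero boundary concentrations are rejected outright because
the scaling divides by them.

## Leading-order closed forms

With `λ₁ = 0` the steady system is linear and decouples: `C₀` solves
`C₀'' = λ₂C₀`, giving `C₀ = cosh(√λ₂ x)/cosh(√λ₂)`; `A₀` and `B₀` are
two-mode combinations `(1+g)·cosh(k x)/cosh(k) − g·cosh(√λ₂ x)/cosh(√λ₂)`
with homogeneous wavenumbers `k_A = √(λ₃/δ_A)`, `k_B = √(λ₄/δ_B)` and
particular amplitudes `g_A = μ_Aλ₂/(δ_Aλ₂−λ₃)`, `g_B = λ₅/(δ_Bλ₂−λ₄)`.

Numerical choices:

* **Overflow policy.** Every ratio is evaluated as
  `exp(k(x−1))·(1+e^{−2kx})/(1+e^{−2k})`; all exponents are nonpositive,
  so `λ₂` up to ~10¹² is usable (naive `cosh` overflows near `k ≈ 710`).
  Accuracy is certified against 40-digit arithmetic in the tests.
* **Degenerate branches.** On the resonance locus `δ_Aλ₂ = λ₃` (likewise
  `δ_Bλ₂ = λ₄`) the generic denominator vanishes and the resonant
  particular solution `∝ x·sinh(√λ₂ x)` applies. The branch switch uses a
  relative threshold of 1e-9 on the denominator; just off the locus the
  generic form is numerically benign (the cancellation error enters at
  ~`g·ε_mach`), and branch continuity is asserted to 1e-4 in the tests.
* **Double-zero limits.** `λ₂ = λ₃ = 0` gives an unforced *a* equation,
  resolved as `A₀ ≡ 1` (the no-reaction uniform state). `λ₂ = λ₄ = 0`
  with `λ₅ > 0` leaves a uniform undepleted source, giving the parabola
  `B₀ = 1 + λ₅(1−x²)/(2δ_B)`; the resonant branch reduces to it
  continuously for `√λ₂ < 10⁻⁸`.

## First-order corrections

At O(λ₁) the corrections satisfy a linear system forced by `A₀B₀`.
Because `A₀B₀` is a product of two-mode cosh sums, product-to-sum
expansion yields modes with the six combined wavenumbers
`θ = k_A ± k_B, k_A ± √λ₂, k_B ± √λ₂`, plus a `2√λ₂` mode and a
constant. `C₁` is solved first; its modes (including the homogeneous
`cosh(√λ₂ x)` term) then force `A₁` and `B₁`. Each particular amplitude
is forcing/(θ² − own rate); homogeneous amplitudes enforce the zero
Dirichlet condition at `x = 1`. In the `A₁` equation the constant
forcings cancel identically, so `A₁` carries no constant mode.

The coefficients are **derived, not transcribed**: the implementation
carries its own derivation and certifies it by evaluating the correction
ODE residuals with *analytic* second derivatives (a correct set shows
pure rounding, asserted below 1e-8, observed ~1e-15) and by agreement to
1e-6 with an independent second-order finite-difference solve of the same
boundary-value system (`correction_oracle_bvp`, optionally Richardson-
extrapolated). The derivation fixes the mode `θ₆ = √(λ₄/δ_B) − √λ₂`
and the `B₁` homogeneous denominator `cosh(√(λ₄/δ_B))`; the constant-mode
amplitudes work out to `C₇`-type denominators `6λ₂` and `2λ₂`.

**Resonance handling.** Rather than deriving every L'Hôpital limit by
hand, any closed-form denominator within a relative 1e-8 of zero raises
`DegenerateModeError` and `first_order_correction` transparently switches
to the numerical boundary-value solve (4001 nodes, Richardson), which
needs no special-casing on the loci. One numeric path covers all
degenerate combinations.

**Validity warnings.** The expansion assumes `λ₁ ≪ 1` with all other
groups O(1). `small_lambda1_profile` warns (`ExpansionValidityWarning`)
when `λ₁ > 0.1` or when the groupings `λ₁μ_A/δ_A` or `λ₁μ_B/δ_B` exceed
0.1 — it is these groupings that scale the correction, so small `λ₁` with
`μ_A/δ_A ~ 10³` still breaks the truncation. The 0.1 thresholds are
package choices for "no longer small".

## Full nonlinear solver

Semi-implicit (IMEX) backward Euler on a uniform grid: diffusion and each
species' own linear decay are implicit; the bilinear `λ₁AB` term uses the
current step; species update in the order C, A, B so the linear cross
couplings use the freshly updated complex. Each update is one
pre-factorised tridiagonal solve (sparse LU, factorised once per run).
The symmetry condition is a second-order ghost-node reflection
(`u₋₁ = u₁`); the Dirichlet node is eliminated from the linear systems,
its known value entering the last interior row's right-hand side, so the
boundary is exactly 1 and the interior exactly consistent with it.

* Defaults `dx = 0.002` (501 nodes), `dt = 0.005`.
* Stopping: `max|uⁿ⁺¹−uⁿ|/dt < 10⁻⁸` per species — a rate, so the test is
  timestep-independent. The scheme's fixed point satisfies the
  central-difference steady equations exactly, so the reported
  `steady_residual` of a converged run sits at the stopping tolerance;
  `converged` additionally requires the residual below `10×` tolerance
  times the solution scale.
* The scheme is first-order in time (only steady states are of interest)
  and second-order in space; both orders are verified by
  step/grid-halving tests, and at `λ₁ = 0` the steady solution matches
  the closed forms to <10⁻³ on the default grid, improving 4× per grid
  halving.
* No adaptive stepping; the explicit `λ₁AB` coupling can destabilise the
  iteration only for extreme `λ₁·dt`, which is detected (non-finite
  values) and reported with advice to reduce `dt`.
* Non-convergence within `max_steps` is a reported flag, not an
  exception.

## Regime classification

Steady `A`-profiles are classified by where their maximum sits. Discrete
profiles need a tie-break: values within a relative 1e-9 of the maximum
form the maximal plateau; if `x = 0` is on the plateau and the boundary
is not, the profile is `centre_maximum`; if the plateau touches the last
two nodes (including the all-constant profile) it is
`monotone_from_boundary`; otherwise `interior_maximum`. At least 101
nodes are required. At `λ₂ = 50`, `μ_A = δ_A = 1` the classification
traverses the three regimes at `λ₃ ≈ 0.042` and `λ₃ ≈ 18.5` — note the
centre-maximum regime ends at a much smaller removal rate than unity.

## Parameter studies

Captions of the canonical studies fix the held parameters but not every
swept value; the package documents its chosen grids in the fixture
registry: `λ₂ ∈ {1, 5, 20, 100, 1000}` for the breakdown sweep, 200
log-spaced `λ₃ ∈ [10⁻², 10²]` for the regime sweep, and a
`26 × 26` log grid (plus the `λ₃ = 0` column) for the central-value
surface. The correction-term study's held set is taken as `λ₄ = 0.2`,
`λ₅ = μ_B = δ_A = δ_B = 1` (the printed caption lists `λ₄` twice and
misspells `μ_B`; this resolution is recorded in the fixture docstring).
Full-model studies (`λ₁ ∈ {0, 2, 20}` at the O(1) set; `λ₁ ∈ {0, 0.01}`
at the stiff set with `δ_A = 0.02`, and its `λ₄ = 10` variant) use the
default grid and are bit-deterministic.

## What the tests do and do not show

The test suite certifies internal consistency (closed forms vs. two
independent numerical routes vs. the nonlinear solver) and the
qualitative orderings of the parameter studies at the documented
parameter sets and grids; acceptance-level solver runs use 20 random O(1)
parameter sets on the `dx = 0.002` grid plus one halving. None of this
validates the biological idealisations themselves — constant boundary
concentrations, first-order removal, a single well-mixed binding partner,
1-D symmetric geometry — so agreement here says the mathematics is solved
correctly, not that a particular tissue obeys it.

## Known limitations

* The correction evaluation targets the O(1) parameter regime the
  expansion assumes; amplitudes are assembled with plain `cosh`, so
  extreme wavenumbers (`λ₂ ≳ 10⁴`) can overflow there — use the solver or
  the leading order (which is overflow-safe) in that regime.
* Near-degenerate leading-order branches are switched, not blended; in a
  band of relative width ~10⁻⁹ around a locus the evaluation carries an
  O(10⁻⁹) model substitution error.
* The time stepper is a relaxation method; transient accuracy is only
  first order and no claim is made about transient dynamics.
* Uniqueness/stability of the computed steady state is not proved;
  initial-condition independence is checked numerically (uniform vs.
  analytic starts agree to the stopping tolerance).
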