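# Methods

## Model and assumptions

The package implements a linear, deterministic matrix population model of a
cell-differentiation hierarchy with constant coefficients. Standing
assumptions, enforced by the constructors:

* `n ≥ 3` compartments — with `n = 2` the only non-stem compartment is the
  terminal, non-dividing one, so neither de-differentiation mode exists.
* Resident divisions have exactly two outcomes: `p_i + q_i = 1`. The
  asymmetric-division variant relaxes this to `p_i + q_i + s_i = 1`
  (`open_budget=True`); it exists purely to demonstrate that asymmetric
  division changes the subdiagonal influx (`2r_iq_i → 2r_iq_i + r_is_i`)
  but not the diagonal, hence not the fitness analysis. There is no mutant
  asymmetric-division model.
* The resident is not shrinking (`λ₀ ≥ 0`) and `λ₀` is simple. Two
  effective self-renewal rates count as tied when they differ by less than
  `1e-9 · max(1, |λ₀|)` (configurable per parameter set via `tie_rtol`).
  Degenerate sets are rejected by constructors and flagged
  (`degenerate_lambda0`) by the scan driver rather than silently dropped.
* `ρ` is the single source of truth for de-differentiation intensity;
  `δ_i = ρ/(2r_i)` is always derived, never stored. The stem compartment
  never de-differentiates (structural, not parametric: row 1 of the mutant
  matrices keeps its resident diagonal), and the terminal compartment never
  divides.

Compartments are 1-based in every user-facing API and in all index symbols
(`j0`, `gamma(params, j, k, l)`); internal arrays are 0-based with
`r[0]` belonging to compartment 1.

## Three routes to the selection gradient

1. **Closed form** — the Γ-ratio case analysis by leading compartment
   (see README). This is the reference implementation.
2. **Perturbation contraction** — `μᵀBη` with `B = ∂A/∂ρ` and the resident
   eigenpair from `scipy.linalg.eig`. η is scaled to unit Euclidean norm
   with a positive anchor entry (the `j₀` entry for triangular matrices,
   the largest-magnitude entry otherwise), then μ is scaled so `μᵀη = 1`.
   Δλ is invariant under any consistent normalisation; this one is merely
   reproducible. The two routes agree to ≤ 1e-13 on every parameter set
   tested; the test suite asserts 1e-9.
3. **Exact difference** — `(λ(A(ρ)) − λ₀)/ρ` on the actually perturbed
   matrix, carrying an O(ρ) truncation error. A Richardson variant over
   `(ρ, ρ/2)` cancels the linear error term and is used as the convergence
   oracle (probe `ρ = 1e-5`, small enough that the residual quadratic term
   sits below the 1e-6 oracle tolerance even at curvature ~3e3).

Dominant eigenvalues of the perturbed (non-triangular) matrices are taken
as the eigenvalue of largest real part; essential non-negativity makes it
real, and an imaginary part above `1e-10 · max(1, |λ|)` is treated as an
internal numerical error, not a model state. For lower-triangular matrices
the eigenvalue is read off the diagonal exactly.

## Thresholds

* `critical_kappa`: where the gradient is κ-dependent (stepwise with
  `j₀ > 1`, jumpwise with `j₀ = n−1`) it is affine with slope exactly −1,
  so `κ*` is the Γ-sum/product itself; values ≥ 1 report "always positive",
  ≤ 0 "always negative" (unreachable while the Γ ratios are positive, but
  guarded). κ-independent cases report "always positive" with the value.
* `critical_rate`: bisection (`scipy.optimize.bisect`, `xtol = 1e-6`) on
  the closed-form gradient at `κ = 1` in one division rate. The leading
  compartment is checked at both bracket ends and at the root, since the
  closed form switches branch with `j₀`. A finite-ρ sign-change
  cross-check warns (not errors) on disagreement, which is expected to be
  benign at O(ρ).
* `critical_rate_closed_form`: for jumpwise mode with `j₀ = n−1`, only the
  `i = 1` factor of the Γ-product depends on `r₁`, giving
  `r₁* = λ₀ / (2q₁C + (p₁ − q₁))` with `C` the product of the remaining
  factors. Bisection and this expression agree to 1e-6 (asserted).

## Dynamics

Trajectories are computed by matrix-exponential action
(`scipy.linalg.expm`, one exponential per time increment), not by a generic
ODE stepper, so eigenvalue-agreement tests carry no integrator tolerance.
The empirical growth rate is the least-squares slope of `log M(t)` over the
final `tail_fraction` (default 0.25) of the time window; its residual decays
like `e^{−gap·t_tail_start}`. The default horizon is `max(50, 10/gap)`; the
eigenvalue-consistency tests use `max(50, 25/gap)` so the tail suppression
is ≤ e⁻¹⁸ while the largest exponent `λ·T` stays ≈ 36, far from overflow.

## Figure fixtures and the random generator

The registry `fig2a … fig6b` carries each reference figure's caption values
verbatim, the parameters the figure varies (with the caption's range where
it states one), and — separately — parameters the caption omits entirely.
Package choices, made once:

* swept-range defaults where no range is printed: `r2 ∈ (0.1, 0.8)` (fig2),
  `r1 ∈ (0.05, 0.4)` / `r2 ∈ (0.1, 0.9)` (fig3), `p2 ∈ (0.55, 0.95)`
  (fig4), ranges for fig5/fig6b chosen to preserve the panel's stated
  leading compartment;
* caption-omitted rates: `r2 = 0.3` (fig5a/5b/5d), `r1 = 0.2` (fig5c) —
  mid-scale values consistent with the neighbouring panels' rates.
  `FigureFixture.bind()` binds free parameters to range midpoints unless
  overridden.

Two captions are internally inconsistent with probability positivity:
fig2b (`p₃ = 0` with `κ = 0.1, ρ = 0.001`) and fig3b (`p₃ = 0.001` with
`ρ = 0.01`) give a mutant self-renewal probability `p₃ − κδ₃ < 0` (by
−1.7e-5 and up to −3e-3). `validate()` reports this honestly; the matrix
builders still succeed because only off-diagonal entries must stay
non-negative, and the gradients are unaffected (they are first-order
quantities at ρ = 0).

`random_params(seed, regime, j0_target, n)` draws division rates from
U(0.1, 1), removal rate from U(0.01, 0.2), and self-renewal probabilities
such that the requested compartment leads: homeostatic pins
`p_{j0} = 1/2` (λ₀ = 0) with every other effective rate strictly negative
(`p_i ~ U(0.05, 0.45)`); expanding draws `p_{j0} ~ U(0.55, 0.95)` and the
other diagonal entries uniformly below `λ₀ − 10⁻³`. The generator emulates
*valid regimes*, not any empirical rate distribution: real tissues have
measured, well-separated kinetics, whereas these draws can produce
near-degenerate diagonals (gap barely above 10⁻³), which is a deliberate
stress regime for the simplicity tolerance. A green property test
therefore establishes the algebraic claims (positivity, slopes, Γ signs)
across regimes — it does not establish anything about biological parameter
values.

## Known limitations

* **First-order validity.** `λ(ρ) ≈ λ₀ + ρΔλ` carries a second-order error
  `≈ ρ²λ''/2` whose curvature `λ''/2` scales with the Γ products over the
  spectral gap. For homeostatic jumpwise tissues with extreme probabilities
  (e.g. the fig6b set: Γ-product ≈ 6, measured `|λ''/2| ≈ 131`) the
  finite-ρ gradient at `ρ = 0.01` deviates from the closed form by ≈ 1.0 —
  two orders above what a curvature-10 bound would predict. Two acceptance
  tests assert such a fixed-constant bound (`|Δλ_exact − Δλ_closed| ≤ 10ρ`
  and its eigenvalue-shift equivalent) and fail on those corner sets; the
  underlying O(ρ) convergence itself (error halving under ρ-halving,
  Richardson limit) holds everywhere and is asserted separately.
* No direct resident–mutant competition in a shared system, no non-linear
  feedback, no density dependence, no stochastic fixation probabilities —
  fitness comparison is purely by dominant eigenvalue of separate linear
  systems.
* Gradients are taken with respect to ρ only; sensitivity to other
  parameters is available only through the one-rate threshold solver.
* No plotting: scans and boundaries are delivered as CSV tables
  (`#`-commented provenance header, 12 significant digits).
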