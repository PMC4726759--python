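# Methods

This note documents the models and derivations behind `cmekit`, the
numerical choices that a user might want to second-guess, what the built-in
fixtures do and do not probe, and the design decisions that were genuinely
open.

## Model class and conventions

A reaction network has species with integer counts `x ∈ ℕ₀^{n_s}`,
reactions with state-change vectors `ν_j` and propensities `a_j(x, t)`,
named positive parameters, optional time-dependent input signals (inlined
into propensities before any derivation) and observables.  Counts are the
canonical unit; each compartment carries a dimensionless system-size
parameter Ω (default 1) and concentration output is counts/Ω.  Ω is the
expansion parameter of the system-size expansion, not a physical litre.

Mass-action propensities built through `network.mass_action` use the
combinatorial convention `a = c·∏ binom(x_i, r_i)`, i.e. `2X → ·` fires at
`c·x(x−1)/2`.  This is stated explicitly because the factor-of-two
difference against the `c·x(x−1)` convention is a classic silent bug; a
user who wants the other convention writes the propensity verbatim as a
general reaction (the dimerization fixture does exactly that).

All derivations start from the CME generator applied to polynomial test
functions, `G f = Σ_j a_j(x,t)(f(x+ν_j) − f(x))`, with `d⟨f⟩/dt = ⟨G f⟩`.
Non-polynomial propensities (e.g. Hill functions) are Taylor-expanded about
the running means before moment-type derivations; the truncation order is
exposed as an option with default equal to the moment order, and the
expansion centre is itself a state symbol so the resulting equations stay
autonomous.

## Finite state projection

The truncation is a hyper-rectangle of user-supplied per-species bounds
intersected with the conservation laws found in the left null space of the
stoichiometry matrix; conserved species are bounded automatically.  There
is no adaptive or moving truncation, and no explicit sink state: lost mass
is tracked only through the defect `1 − Σ p`, which is an equivalent but
smaller formulation.  Moments of an FSP solution are renormalised by
`1 − defect`, with the defect reported in the trajectory flags so a
consumer can judge the bias.  Truncation bounds are chosen by the user;
the defect readout is the instrument for checking they were large enough
(the shipped gene-expression analyses run at defect ≤ 0.3%).

## Moment equations and closures

Raw moments `⟨x^I⟩` for `1 ≤ |I| ≤ m` are the integration variables; the
central-plus-mean representation is derived independently through
`d⟨(x−μ)^I⟩/dt = ⟨G(x−μ)^I⟩ − Σ_i I_i ⟨(x−μ)^{I−e_i}⟩ μ̇_i`, and the two
routes are checked against each other symbolically in the tests.  Closures
substitute every raw moment of order > m:

* **low dispersion** — central moments above m vanish;
* **zero cumulants** — cumulants above m vanish; higher raw moments are
  rebuilt by the multivariate moment–cumulant recursion (peeling one unit
  off the first occupied coordinate);
* **mean field** — `⟨x^I⟩ = ⟨x_s⟩⟨x^{I−e_s}⟩` with `s` the
  lexicographically first species present in `I`.  The factorisation split
  is under-determined in the literature; this canonical "peel" rule is our
  documented choice, which matters to anyone comparing numbers against
  other implementations of a "mean-field" closure;
* **derivative matching** — the product form `∏ ⟨x^J⟩^{γ_J}` with
  exponents solving the binomial matching system (exact for a point mass).
  The exponent systems are solved once per `(n_s, m, I)` and cached.
  Started from a deterministic state with zeros (so some raw moments are
  exactly 0 raised to negative powers), these systems routinely diverge;
  divergence is caught and reported as `failed`, never masked, and the
  benchmark grid shows it as a missing entry;
* **user** — a caller-supplied substitution map, validated for
  completeness.

Deterministic initial counts give initial raw moments `x₀^I` (equivalently
zero central moments); user-specified initial moments are accepted through
the symbolic system's initial-condition slots.  Concentration units divide
counts by the compartment Ω before derivation, keeping a single derivation
path.

## System size expansion

Writing `x = Ωφ + √Ω ξ` and collecting powers of `h = Ω^{−1/2}` yields the
RRE for `φ`, the LNA covariance, the EMRE mean correction and the IOS
covariance correction.  Instead of transcribing the (long) textbook
correction formulas, the expansion is executed mechanically in sympy: the
generator applied to ξ-monomials is expanded in `h`, formal expectations
replace ξ-monomials by order-resolved symbols `m_K^{(k)}` (zero whenever
`|K| + k` is odd), and the tracked blocks are

| block | meaning | enters at |
|---|---|---|
| φ | macroscopic mean (RRE) | h⁰ |
| Σ = m₂⁽⁰⁾ | LNA covariance of ξ | h⁰ |
| a₁ = m₁⁽¹⁾ | EMRE mean correction (counts: mean = Ωφ + a₁) | h¹ |
| m₃⁽¹⁾, m₄⁽⁰⁾, m₂⁽²⁾ | third/fourth ξ-moments and the IOS covariance correction (counts: cov = ΩΣ + m₂⁽²⁾ − a₁a₁ᵀ) | h¹/h⁰/h² |

The derivation asserts internally that all divergent `h^{−1}` terms cancel
exactly against the macroscopic drift — any mis-scaled propensity trips
this assertion instead of producing silently wrong corrections.  Each
reaction is brought to macroscopic scaling by splitting Ω into the
expansion symbol and a frozen numeric copy: a degree-d propensity is
multiplied by `(Ω_ref/Ω)^{d−1}`, unchanged at the true volume.  The
correctness evidence is structural rather than formula-by-formula: linear
networks reproduce the exact CME moments at every order, corrections
vanish symbolically when the Hessians and sub-leading terms vanish, the
IOS/EMRE/LNA/RRE blocks nest exactly, and the IOS variance lands within
3·10⁻⁵ of the FSP oracle on the dimerization fixture where the LNA is off
by 0.6%.

A single Ω is used per network (the expansion with genuinely distinct
compartment scalings is out of scope); multi-compartment models with equal
volumes, like the shipped signalling chain, are unaffected.

On the dimerization fixture (propensity `k₂x(x−1)`, macroscopic rate
`k₂φ²`) the EMRE correction is *positive*: the sub-leading `−k₂φ` term
dominates and moves the mean up towards the FSP truth, which lies above
the RRE prediction under this propensity convention.  With the halved
`c·x(x−1)/2` convention the usual "bimolecular depletion lowers the mean"
intuition applies; the sign of the correction is convention-dependent, the
error reduction versus the RRE is not.

## Method of conditional moments

Low-copy species (finite provable range, e.g. promoter occupancy bound by
a conservation law) are enumerated as modes `y`; high-copy species `z` are
tracked through moments conditional on the mode.  Integration uses
weighted moments `w_I^y = p(y)·E[z^I|y]`, whose master-equation dynamics
are plain ODEs — this converts the normalised description's DAE (singular
wherever `p(y) = 0`) into a form with no divisions.  The normalised DAE
view (unit mass on probability rows, `p(y)`-weighted mass on moment rows)
is retained and integrable through the symbolic engine's DAE path, which
handles structurally-zero mass rows by index-1 algebraic solves and
state-dependent diagonal masses by regularised division.

Closure expressions need the conditional normalisation `1/p(y)`; it is
regularised as `p/(p² + ε²)` with ε = 10⁻¹², which tends smoothly to zero
for empty modes (the true limit of the closed weighted moments) and
introduces an O(ε·moments) error only while `p ≈ ε`.  Conditional moments
are *reported* only where `p(y) > 10⁻¹⁰`, and NaN otherwise — an empty
mode has no conditional distribution to report.

Propensities are evaluated exactly in `y` (modes are numeric) and must be
polynomial in `z`; a jointly nonlinear propensity is therefore expanded in
`z` only, holding the mode exact.  Two degenerate partitions pin the
derivation down: no high-copy species ⇒ the system is exactly the FSP on
the mode space; no low-copy species ⇒ exactly the moment equations of
order m.  Both equivalences are asserted to integration tolerance in the
tests and are the strongest structural checks of the derivation.

## Stochastic simulation

The direct and next-reaction methods serve time-homogeneous networks; the
modified next-reaction method integrates each reaction's propensity
against a unit-exponential internal clock, so time-dependent propensities
are sampled exactly whenever `∫a_j dt` has a closed form (sympy attempts
the antiderivative automatically; the caller may supply one) and by
adaptive quadrature with bracketed root-finding otherwise (absolute
tolerance 10⁻¹⁰).  Fixed delays put the full state change ν_j into a
completion queue applied at `firing + delay`; distributed delays are not
supported.  Simultaneous tentative firings break ties to the lowest
reaction index (a measure-zero event that still needs a deterministic
rule).

Every path draws from `numpy.random.default_rng((master_seed, path_index))`
— a counter-based seeding that makes ensembles bit-reproducible regardless
of execution order.  Output is zero-order-hold sampling on the requested
grid, bounding memory for 10⁴-path ensembles; full event sequences are not
stored.  Moment estimators carry central-limit standard errors (the
variance of the variance uses fourth moments via the delta method), and
second central moments carry the n/(n−1) correction.

## Sensitivities

Forward order 1 augments `n` states to `n(1+n_θ)`; order 2 adds the
`n·n_θ(n_θ+1)/2` symmetric second-order states with the full chain rule.
DAE bases propagate their mass-matrix diagonal to every sensitivity block.
The adjoint sweep (ODE bases only) integrates `dλ/dt = −Jᵀλ` backward
segment-wise between measurement times with exact jump updates at each
datum — no delta smoothing — accumulating `∫λᵀ∂f/∂θ dt` alongside, plus
the `λ(0)ᵀ∂x₀/∂θ` boundary term and the observables' explicit parameter
dependence.  Finite differences default to a central step of 10⁻⁶ relative
with a 10⁻⁸ absolute floor; this default matters when comparing gradient
methods, so it is fixed here.  Tight tolerances (10⁻¹⁰/10⁻¹²) are used for
objective/gradient integrations because gradient agreement at 10⁻⁶
relative leaves little room for solver noise.

## Numerical choices

* Default integration tolerances 10⁻⁸ relative / 10⁻¹⁰ absolute (LSODA for
  derived dense systems, BDF with the sparse generator as Jacobian for the
  FSP).  Moment systems are stiff; analytic Jacobians are always compiled.
* Symbolic lowering runs common-subexpression elimination before lambdify;
  derived moment systems share many subterms.
* Raw moments are integrated in count units; magnitudes up to ~10⁶ for the
  shipped fixtures are well inside double precision at these tolerances.
* Trajectory diagnostics (negative variances, non-PSD covariance matrices)
  are flagged, never clipped.
* SBML import maps kinetic laws verbatim to general propensities, splits
  reversible laws by sign of the expanded terms, promotes local parameters
  with reaction-prefixed names, and rounds non-integer amounts with a
  warning.  How SBML concentration-based rate laws should map onto
  count-based propensities is not standardised; here compartment sizes are
  substituted numerically and amounts are treated as counts, which is the
  convention a counts-based CME needs.

## Fixtures: what they probe, and what they don't

* `birth_death` (k=10, γ=1, x₀=0) — the linear, analytically solvable
  case: Poisson law, mean = variance = 10(1−e^{−t}).  Exactness here tests
  the derivations, not the closures (linear networks close on their own).
* `dimerization` (k₁=4, k₂=0.01) — minimal nonlinearity; exposes closure
  and expansion corrections with a cheap FSP oracle.
* `three_stage_gene_expression` — promoter switching with feedback
  (τ_on=0.1, τ_off=0.3, τ_fb=0.005 per protein, k_m=4, k_p=2, γ_m=1,
  γ_p=0.2, started off).  The defaults were chosen so the stationary
  protein distribution (mean ≈ 13, bimodal-ish between the off-branch and
  the on-branch at ≈ 40) remains coverable by a ~3600-state truncation at
  defect ≤ 0.3% — large enough for visible method differences, small
  enough for the FSP to stay a fast certified oracle.
* `timedep_birth` (a(t) = 5(1+sin t)) — inhomogeneous Poisson process with
  closed-form antiderivative: X(2π) ~ Poisson(10π) tests the modified
  next-reaction method exactly.
* `two_compartment_chain` — an input-driven activation/dimerization/
  nuclear-import cascade with a 5-step chain modelling delayed export
  (S₀=50, k_act=0.1, k_dim=0.05, k_imp=0.2, k_ch=0.3, input
  `u(t) = e^{−t/5}(1−e^{−t})`); exercises compartments, time-dependent
  inputs and the n=8 sensitivity machinery.

These fixtures are deliberately small and well-mixed.  Passing tests show
the derivations and integrators are correct at desk scale; they do not
show that any particular closure is adequate for a *real* network (closure
accuracy is problem-specific — that is why the comparison harness exists),
nor do they probe extrinsic noise, cell division, spatial effects, or
state spaces beyond ~10⁵ states where the dense-linear-algebra-free FSP
path would need Krylov exponential integrators (not implemented).

## Known limitations

* FSP truncations are static; no adaptive state-space growth.
* No tau-leaping or other approximate accelerated SSA variants.
* Adjoint sensitivities exclude DAE bases (forward order 1–2 covers them).
* The SSE assumes one common system-size parameter.
* SBML events, rules, function definitions and hierarchical models are not
  supported.
* Sample-path generation is pure Python; 10⁴-path ensembles of the shipped
  fixtures take tens of seconds, which is the intended scale.
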