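# Methods

## Scope and model

`immobead` models a bead-entrapped enzyme operated in a fixed bed, under
the standard idealizations: isothermal operation, uniform enzyme loading,
irreversible single-substrate Michaelis–Menten (MM) kinetics with no
inhibition, constant effective diffusivities, negligible external film
resistance, and bulk substrate concentration constant over a bead's
residence time. Two layers follow from these assumptions:

1. **Reactor layer.** At steady state the outlet concentration of a
   plug-flow bed satisfies the integrated MM relation
   `Km·ln(S0/St) + (S0 − St) = Vmax·t` with residence time
   `t = ε·VR/Q`. Note the residence time uses the *interstitial* volume
   ε·V<sub>R</sub>: only the liquid-filled fraction of the bed holds the
   flowing substrate. This relation is exact, so it serves both as the
   forward model of the synthetic-data generator and as the basis of the
   estimator.

2. **Bead layer.** Intraparticle diffusion–reaction in dimensionless form
   (concentrations scaled by S₀, lengths by the bead radius R, time by
   R²/D<sub>s</sub>):

   ```
   ∂Cs/∂τ = ∇²Cs − 9φ²·Cs/(1 + β·Cs)
   ∂Cp/∂τ = λ∇²Cp + 9φ²·Cs/(1 + β·Cs)
   ```

   on the axisymmetric cross-section, with Cs = 1, Cp = 0 on the surface,
   zero normal derivative on the symmetry axis and midplane, and zero
   initial interior concentrations. The Thiele modulus is defined as
   `φ = (R/3)·√(Vmax/(Km·Ds))` — the unique normalization for which the
   source coefficient is exactly 9φ², i.e. 9φ² = Vmax·R²/(Ds·Km). With
   `β = S0/Km`, β → 0 recovers first-order kinetics (which has the closed
   form `C(ρ) = sinh(3φρ)/(ρ·sinh 3φ)` used as the solver oracle) and
   β ≫ 1 approaches zero-order.

## Estimator

Writing conversion X = (S₀ − S<sub>t</sub>)/S₀, the integrated relation
rearranges *exactly* to `ln(1−X)/t = (S0/Km)(X/t) − Vmax/Km`. The package
fits y = ln(1−X)/t on x = X/t by unweighted ordinary least squares —
matching the graphical method the linearization was designed for — and
back-transforms `Km = S0/slope`, `Vmax = −intercept·Km`. Two numerical
points matter:

* y is evaluated as `(ln St − ln S0)/t`, never via `1 − X`: forming 1−X
  first loses ~6 significant digits once X ≈ 1 − 1e−10 and visibly biases
  high-conversion fits.
* Observations with X ≥ 1 − 1e−12 have an undefined log term. They are
  rejected with a named error by default, or dropped with a logged warning
  on request (`on_complete="drop"`); they are never clipped, which would
  bias the slope. A fit needs at least two usable, distinct points.

A nonpositive slope (physically: no saturable consumption signal) raises
`EstimationError` rather than returning a negative K<sub>m</sub>.

Rate constants k₁, k₋₁ are carried as optional metadata only; they are not
identifiable from (K<sub>m</sub>, V<sub>max</sub>) and no routine
estimates them. k₂ = V<sub>max</sub>/[E]₀ is computed only where the
enzyme load is supplied.

## Units

Everything internal is g, L, cm, min. Constructors accept per-second rates
(`MMKinetics.from_seconds`) and convert on ingestion, since published
V<sub>max</sub> and k₂ values for this system are usually quoted per
second while the diffusivity is per minute; one internal system avoids
silent mismatches.

## Discretization

**1-D radial solver** (`steady_sphere_1d`): second-order central
differences on a uniform grid in ρ ∈ [0, 1]; the removable singularity at
the center uses the symmetry limit of the spherical operator,
`6(C₁ − C₀)/h²`.

**2-D axisymmetric solver** (`steady_axisymmetric`): linear (P1) finite
elements on a polar-structured triangulation of the quarter disc — rings
at ρ = j/n, near-uniform angular spacing, a fan around the center node —
with the cylindrical weight r in all integrals. The surface ring lies
exactly on the unit circle, so Dirichlet data are imposed without
geometric error at the nodes. The reaction/mass term uses **row-sum
lumping of the exact weighted mass matrix**, `m_i = Σ_T A_T(r_i + 3r̄_T)/12`.
This detail is load-bearing: naive vertex-quadrature lumping weights node
i by r_i, which vanishes on the symmetry axis and deletes the reaction
term there, inflating the L∞ error near the pole by an order of magnitude.
With row-sum lumping the scheme is second order (observed L2 order ≈ 1.98
against the β = 0 closed form) and resolves φ = 10 to L∞ ≈ 4e−3 at n = 64.

`n` is the resolution parameter (nodes per unit radius); meshes below
n = 16 are rejected as unreliable.

**Nonlinear solve**: Picard iteration with the MM denominator frozen —
each iterate solves a linear problem whose matrix is an M-matrix, so
iterates respect the maximum principle 0 ≤ Cs ≤ 1 — with under-relaxation
0.8, then a damped-Newton finish (step halving on residual increase) to
drive the algebraic residual below 1e−10 (1-D) / 1e−8 (2-D), capped at 500
iterations. Non-convergence raises `SolverError` carrying the last
residual; in practice β = 0 converges in one linear solve and β = 50 in a
handful of iterations.

**Transient** (`transient_solve`): backward Euler on the lumped-mass
system with a geometrically growing step (dt₀ = 1e−4, ×1.25 per step,
capped at 0.25): the early surface-layer dynamics are fast, while the late
approach to steady state tolerates large implicit steps because the fixed
point of backward Euler *is* the discrete steady state. The product update
reuses the identical discrete source term as the substrate update, so at
λ = 1 the sum W = Cs + Cp obeys the exact discrete heat equation and
relaxes to W ≡ 1 to solver precision (observed ~1e−13 by τ = 10) — the
conservation test is a property of the scheme, not a tolerance tuned to
it. Backward Euler is first order; snapshots at moderate τ carry O(dt)
time-discretization error, which is why accuracy contracts are stated at
the steady limit rather than mid-transient.

**Effectiveness factor**: η = (1+β)·⟨Cs/(1+βCs)⟩ with the volume average
taken by Simpson's rule (ρ² weight) in 1-D or the lumped FEM weights in
2-D; η is clamped to ≤ 1 against round-off overshoot at φ → 0. Transient
snapshots are flagged unconverged and rejected — η is defined for steady
fields only.

## Synthetic data

The generator emulates a conversion campaign over the experimental design
space — S₀ ∈ {1, 5, 10, 50, 100} g/L crossed with residence times
{5, 10, 20, 40, 60, 90, 120} min — with truth
(K<sub>m</sub> = 3.38 g/L, V<sub>max</sub> = 0.134 g/(L·s)) at the center
of the reported parameter range for this system. Measurement noise is
mean-one multiplicative lognormal on S<sub>t</sub>: a spectrophotometric
read-out is positive with roughly proportional error, and the mean-one
parameterization (σ² = ln(1+cv²), mean −σ²/2) keeps the noiseless
expectation equal to the forward model. Draws are clipped to (0, S₀],
which truncates the upper tail when the true outlet is close to S₀ — a
deliberate physicality constraint, so the mean-one property holds exactly
only away from the clip.

What the generator does **not** emulate: enzyme leakage over operating
time (entrapment efficiency is provided as arithmetic only), assay
nonlinearity, autocorrelated drift, or inlet-concentration error. Passing
recovery tests therefore demonstrate estimator correctness under the
assumed error model, not robustness to real-world systematic error.

A note on the default truth: with V<sub>max</sub> = 8.04 g/(L·min), most
of the long-residence-time grid reaches numerically complete conversion
(X ≥ 1 − 1e−12) and is excluded by the estimator, leaving 2–3 informative
points per S₀. The exact linearization still recovers the truth to
round-off from noiseless data, but under noise the sparse designs (small
S₀ especially) are fragile — the 5 %-noise median |K̂m/Km − 1| ≈ 0.06
overall masks ≈ 0.24 at S₀ = 1 g/L. This is a faithful property of the
design space, not an estimator defect.

## Design choices that were genuinely open

* **Sign convention of the linearized fit.** Printed forms of this
  linearization circulate with the slope/intercept signs flipped; direct
  algebra from the integrated relation fixes slope = +S₀/K<sub>m</sub>,
  intercept = −V<sub>max</sub>/K<sub>m</sub>, which is what exact data
  produce. The package follows the algebra.
* **Residence time.** t = ε·V<sub>R</sub>/Q (interstitial holdup), which
  reproduces both reference operating points (5.04 mL/min ↔ 5 min and
  0.21 mL/min ↔ 120 min for V<sub>R</sub> = 60 cm³, ε = 0.42).
* **Thiele normalization.** φ = (R/3)·√(Vmax/(Km·Ds)), so that 9φ² is the
  PDE source coefficient; other conventions differ by the factor 3
  (surface-to-volume of a sphere).
* **λ default.** D<sub>p</sub> is rarely measured; λ defaults to 1, where
  the W-reduction holds exactly and is testable.
* **Per-panel steady solves.** Each residence time yields its own fitted
  kinetics, hence its own (φ, β), and each field is an independent steady
  solve; the transient is provided for start-up studies, not coupled to
  reactor dynamics.

## Known limitations

* No external film resistance, enzyme deactivation, product/substrate
  inhibition, or reactor-scale axial dispersion.
* The 2-D solver assumes uniform surface data; with non-uniform Dirichlet
  data the polar mesh's skinny center triangles would degrade (but not
  break) accuracy.
* Backward Euler limits mid-transient temporal accuracy to first order.
* Monte-Carlo calibration values quoted above use 200 replicates at the
  default seed; they are regression anchors, not population constants.

## Problem sizes

Defaults were chosen so the full test suite runs in well under a minute:
mesh n = 64 (≈ 6.5k nodes) for accuracy-critical checks, n = 32 for
transient runs, 50-truth recovery sweeps, and 200-replicate noise
calibrations. All scale up by passing larger `n`/`replicates`.
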