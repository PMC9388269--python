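# Methods

## Model and assumptions

The model treats racism and corruption as transmissible conditions in a
single well-mixed population with recruitment Λ (individuals/year) and a
uniform removal rate μ (1/year) from every compartment; there is no
contagion-induced mortality.  Seven compartments partition the population:
susceptible S, corrupted C, racist R, co-affected C1, and recovered classes
R1 (from corruption), R2 (from racism), R3 (from both simultaneously).
Corruption is acquired by standard incidence λ_C = (β/N)(C + ω1·C1) —
contacts scale with composition, not raw numbers — while racism follows mass
action, λ_R = α(R + ω2·C1), so its pressure grows with the absolute number
of racist individuals.  The asymmetry matters: it makes α a per-individual
rate (its natural scale is μ(γ2+μ)/Λ ≈ 3×10⁻⁶ at the reference values, not
order one), and it places the standard-incidence quotient terms at the heart
of the bifurcation curvature below.  Already-affected individuals acquire
the second contagion at modified rates (factors η, ξ ≥ 1); the co-affected
revert to single classes at σ1, σ2 or recover jointly at γ3; recovery
confers temporary protection lost at θ1–θ3.  Time is measured in years
throughout, purely as a labelling convention.

Because every transfer term cancels in the column sum, N' = Λ − μN exactly
(verified symbolically in the test suite), the simplex
Ω = {x ≥ 0, N ≤ Λ/μ} is forward-invariant, and every equilibrium has
N* = Λ/μ.

Two reduced systems are first-class: the racism-only submodel on (S, R, R2)
and the corruption-only submodel on (S, C, R1), each the restriction of the
full vector field to its invariant face.  All code paths share one 7-vector
state layout with absent compartments pinned to zero.

## Parameters

The sixteen rates are validated on construction: all nonnegative, Λ and μ
strictly positive (the contagion-free susceptible pool is Λ/μ), ω1, ω2 ≥ 1.
The reference set used throughout (`reference_parameters`) is Λ = 50, μ = 0.01,
σ1 = 0.6, σ2 = 0.7, η = 1.3, ξ = 1.2, θ1 = 0.3, θ2 = 0.25, θ3 = 0.2,
γ1 = 0.007, γ2 = 0.006, γ3 = 0.008, with the transmission rates α, β free
and ω1 = ω2 = 1 by default (the source study states no values for the ω's;
the defaults are documented as this package's choice, not asserted as the
study's).  An exploratory `racism_incidence="standard"` switch divides the
racism term by N; the default is mass action, and all closed forms quoted
here refer to the default.

## Reproduction numbers

F and V are assembled at the contagion-free point over infected compartments
(C, R, C1) for the full model — F is then upper-triangular, so the spectral
radius of F·V⁻¹ is exactly max{R_r, R_c} with R_r = Λα/((γ2+μ)μ) and
R_c = β/(γ1+μ); the co-affected column never feeds back at first order.
Both the spectral radius and the closed form are computed and recorded, and
their agreement to 1e−10 relative over a thousand random draws is an
acceptance property.

## Equilibria

Submodel endemic points are closed-form.  Factoring the trivial root out of
the equilibrium force-of-infection equation leaves a *linear* equation, so
above threshold the endemic force is unique:

    λ_R* = (γ2+μ)(θ2+μ)(R_r−1)/(γ2+θ2+μ),
    λ_C* = (γ1+μ)(θ1+μ)(R_c−1)/(γ1+θ1+μ),

with compartments recovered from flow balances (R2* = γ2R*/(θ2+μ) etc.).
Requests below threshold raise a dedicated error.  An independent bisection
oracle (solve the linear balance system at a trial force, re-evaluate the
force, locate sign changes) confirms uniqueness above threshold and absence
below in the tests.

The full coexistence equilibrium has no tractable closed form and is found
by Newton iteration (scipy's Powell hybrid) from a seed schedule: the
simulator's long-time state, the two boundary equilibria, their mixture, an
optional user guess, and ten seeded log-normal perturbations.  A root is
accepted only if the independently re-evaluated residual is below
1e−8·max(1, Λ/μ) and every compartment exceeds 1e−9·max(1, Λ/μ) — the floor
prevents a boundary root with numerically-zero compartments from
masquerading as interior.  Failure is a result, not an exception.

**Coexistence is not guaranteed by R_rc > 1.**  Each contagion depresses the
susceptible pool at its own endemic point (S* = S⁰/R for the standard-
incidence contagion and likewise for mass action), so an unbalanced pair
leads to competitive exclusion: e.g. (R_r, R_c) = (2.55, 3.38) at the
reference rates converges to the corruption-only boundary.  The interior
equilibrium exists and attracts when each contagion can invade the other's
boundary equilibrium, i.e. when the full Jacobian at both single-contagion
endemic points has a positive leading eigenvalue; the co-affected channel
(σ's feeding back, ξ/η cross-acquisition) is what opens this window, and at
the reference rates it requires both reproduction numbers large and
comparable (≈ 4–6 at γ3 = 0.008).

## Stability

Jacobians are generated symbolically once (sympy) and evaluated numerically;
a central-difference oracle checks them at random states in the tests.
Classification uses a zero tolerance of 1e−8 relative to the spectral
radius: stable iff all real parts < −tol, marginal iff none exceeds +tol.
At the contagion-free point the spectrum is closed-form
{−μ, β−(γ1+μ), αΛ/μ−(γ2+μ), −(σ1+σ2+γ3+μ), −(θ1+μ), −(θ2+μ), −(θ3+μ)},
which forces stable ⟺ R_rc < 1; a 500-draw-per-model concordance test
exercises this.

The racism endemic cubic is assembled from the Jacobian entries (the monic
characteristic polynomial; its constant term is minus the determinant) and
judged by the Routh–Hurwitz array (stable ⟺ a1 > 0, a3 > 0, a1a2 > a0a3),
with a zero pivot reported as indeterminate rather than ε-perturbed.  The
verdict is cross-checked against direct eigendecomposition on 200
supercritical draws.

The global-stability (Lyapunov) check samples Ω uniformly (Dirichlet with a
slack coordinate) and verifies two inequalities per sample: the certificate
dR/dt ≤ (γ2+μ)(R_r−1)R — algebraically αR(S−Λ/μ) ≤ 0, which holds on Ω for
*every* parameter set — and its sub-threshold consequence, the decrease
d(infected)/dt ≤ 0, which genuinely fails above threshold and is reported
(not raised) there.  The corruption variant uses S/N ≤ 1.  The full model is
unsupported: no analogous bound is available.

## Bifurcation at the corruption threshold

With β as the bifurcation parameter, the contagion-free Jacobian has a
simple zero eigenvalue at β* = γ1+μ provided R_r < 1 (R_r = 1 simultaneously
is a codimension-2 point and rejected).  Null vectors come from the SVD of
J(E⁰; β*); u is scaled so its C-component is +1 and v so v·u = 1 (the signs
of a and b are invariant under such positive rescalings).  The coefficients
use *full* Hessian sums over all seven components, with second partials
generated symbolically: only f2's Hessian survives on the support of u, and
the standard-incidence quotient contributes ∂²f2/∂x2² = −2β*/N⁰ and
∂²f2/∂x2∂x5 = −β*/N⁰, giving a = −2v2u2β*(u2+u5)/N⁰ < 0 and b = v2u2 = 1
under the normalization — a forward bifurcation, confirmed against a
directional finite-difference oracle on 200 admissible draws.  Two
structural corrections to the printed derivation are carried in the audit:
the left null vector has a nonzero co-affected component
v4 = v2(β*ω1+σ1)/(σ1+σ2+γ3+μ) (immaterial for a and b because f4's Hessian
vanishes on the support of u), and the transversality coefficient is v2u2,
not βv2u2 (same sign).

## Sensitivity and thresholds

Elasticities SI(p) = (∂R/∂p)(p/R) have exact closed forms (+1 for the
parameters the numbers are linear in; −γ/(γ+μ)-type expressions otherwise)
and are each cross-checked by a central difference of the NGM spectral
radius with relative step 1e−6 (absolute fallback 1e−9 at p = 0).  The
gamma1/mu indices of R_c sum to −1 exactly — one shared denominator — which
the audit uses against the reported pair.  Threshold values solve R = 1 in
one parameter in closed form and are verified against brentq root-finding on
the closed form; absence of an admissible crossing returns None.

## Simulation and scenarios

Integration uses LSODA at rtol 1e−8 / atol 1e−10 with 400 output samples by
default; sub-round-off negatives (≥ −1e−9) are clipped before incidence
terms and at output.  A tolerance-tightening test bounds solver dependence
of terminal states below 1e−6 relative.  Convergence detection declares a
trajectory steady when every compartment's variation over a trailing window
is within tolerance relative to max(|terminal|, 1e−6·N) — the floor keeps
extinct compartments from failing the relative test.
`integrate_to_steady_state` chains 2000-year chunks (up to 40000 years)
until the window is quiescent; coexistence runs typically settle within
~16000 years at the reference rates, a horizon chosen for the slow
demographic time-scale 1/μ = 100 years.

The scenario generator defines the study conditions.  It anchors on the
reference rates, jitters the non-transmission rates by ±20%, then solves the
transmission rates backwards from target reproduction numbers so every
regime's threshold position holds by construction (and is re-verified):

* `subcritical`: both numbers drawn in [0.1, 0.6] — comfortably below the
  0.9 contract so sub-threshold decay is observable within a few thousand
  years;
* `supercritical`: both drawn in [3, 6] with rejection until both boundary
  equilibria are transversally unstable (mutual invasibility), so an
  interior coexistence attractor exists — see above;
* `racism_only` / `corruption_only`: the other transmission rate zeroed,
  the active number drawn in [1.5, 4].

The γ3 sweep experiments (terminal co-affected class versus the joint
recovery rate over 0.54–0.73) use the reference rates with transmission
solved for (R_r, R_c) = (40, 40): a boundary-eigenvalue scan shows mutual
invasibility at γ3 ≥ 0.54 requires both numbers ≳ 27, and the source study
states no transmission rates for that experiment.  Under these conditions
the terminal C1 decreases strictly and monotonically in γ3.

What the generator does *not* emulate: demographic stochasticity, contact
heterogeneity, age or spatial structure, behaviour change, or any coupling
of the two contagions beyond the model's cross-acquisition terms.  Passing
tests therefore certify the implementation against the model's own
mathematics, not the model against data.

## Discrepancy audit

Several reported headline numbers are irreconcilable with the model's own
closed forms at the reference values: R_r = 3.51 at α = 1.37 (closed form:
428125 — the mass-action α is dimensionally a per-individual rate),
R_c = 6.03 at β = 1.51 (closed form: 88.82), the sensitivity entries −0.85,
−0.546, −0.346 and a +1 recruitment index for R_c (which has no Λ
dependence), and the thresholds γ2 > 0.059, γ1 > 0.508, β < 0.17, α < 0.322
(the γ1 value is consistent only with an unstated β = 0.518).  The audit
recomputes every such quantity at run time and tabulates computed versus
reported with a consistency flag; nothing in the test suite asserts a
reported-but-inconsistent value as truth.

## Known limitations

* The interior coexistence equilibrium is found numerically; in regimes far
  from the generator's (e.g. extreme rate ratios) the seed schedule may
  fail, which is reported as not-found with the best residual.
* Global stability of endemic equilibria is exercised dynamically
  (convergence from scattered starts), not certified by a constructed
  Lyapunov function.
* The marginal classification band (1e−8 relative) is a numerical
  convention; spectra genuinely on the axis are resolved only up to it.
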