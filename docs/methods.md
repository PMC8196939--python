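# Methods

## Model and reduction

The full model has three compartments S (susceptible), I (infected), V
(vaccinated).  Between pulses

    dS/dt = A - dS - βSI + vI + θV + cI/(b+I)
    dI/dt = βSI - (d+v)I - cI/(b+I)
    dV/dt = -(θ+d)V

and when S reaches the threshold S_T from below the pulse
(S, I, V) ↦ ((1−q)S, I, V + qS) fires.  The total N = S+I+V obeys
dN/dt = A − dN between pulses and is conserved across them, so
N(t) = A/d + (N₀−A/d)e^{−dt} along the whole hybrid orbit; `simulate3d`
checks this law as a structural invariant.  On the attracting manifold
N = A/d the dynamics reduce to the planar system used everywhere else
(`model_core`, `simulate`), with V = A/d − S − I.

The planar flow is studied on the invariant triangle
D = {S, I ≥ 0, S+I ≤ A/d}.  Simulations raise a domain-exit error if an
orbit leaves D by more than a tolerance (default 1e-6) instead of
silently continuing.

## Parameters

| name | meaning | unit | baseline |
|------|---------|------|----------|
| A    | recruitment rate | ind/time | 7 |
| d    | natural death rate | 1/time | 0.7 |
| β    | transmission coefficient | 1/(ind·time) | 1 (or 0.8) |
| v    | spontaneous recovery rate | 1/time | 4 |
| θ    | vaccine waning rate | 1/time | 0.1 |
| c    | maximal treatment rate | ind/time | 2.5 |
| b    | treatment half-saturation | ind | 1 |
| q    | pulse vaccination fraction | — | 0.22 |
| S_T  | susceptible trigger threshold | ind | 8 (or 6.3) |

The baseline values are the preset `fig1`; `fig2a`/`fig2b` change β to
0.8 and S_T to 6.3/8.  Validation requires 0 < q < 1 and
0 < S_T < A/d (otherwise S never reaches the trigger).  The degenerate
limits q = 0 and S_T = 0 are admitted only by the raw-value entry point
`mu2_closed_form`, used for limit evaluation and parameter scans.

## Equilibrium analysis

Equilibria of the planar flow satisfy S + I = A/d (sum the two
equations), so endemic states are roots of I² + a₁I + a₂ = 0 with
a₁ = b + (d+v)/β − A/d, a₂ = (c+b(d+v))/β − bA/d.  R₀ < 1 does not
guarantee elimination: for A above A₁ = bd + d(d+v)/β the saturating
treatment bends the endemic branch backward and two endemic states
coexist for R̂₀ < R₀ < 1 (backward bifurcation).  Stability at an
endemic point uses H(I) = θ + d + βI − cI/(b+I)², which equals minus the
Jacobian trace there; the node/focus distinction comes from the
discriminant of the Jacobian.  H is sometimes written with an extra +q
for the continuously-vaccinated variant; the planar system contains no
q, so the default omits it and a `paper_literal` switch restores it for
comparison.  Exact boundaries (|R₀−1| or the quadratic discriminant
below 1e-9 relative) are labelled `"boundary"` rather than forced into a
case; a double root is reported once with multiplicity 2.

## Hybrid simulation and event detection

Integration uses `scipy.integrate.solve_ivp` (DOP853, rtol 1e-10,
atol 1e-12 by default — the derivative stack of the Poincaré map needs
integration errors far below its finite-difference steps).  The pulse is
a terminal event on S − S_T with upward crossing direction; the state at
a pulse time is the pre-pulse value and the post-pulse value is recorded
separately (left-continuous convention).  Since q > 0, the post-pulse
state (1−q)S_T sits strictly below the threshold and cannot retrigger.

**Grazing passages.**  Near the tangency of the flow with the threshold
line the excursion of S above S_T is shorter than an adaptive integrator
step, and a plain terminal event never sees a sign change at step
endpoints (concretely: for `fig2b` and section heights I₀ ∈ (1.14, 1.156)
the step endpoints straddle a maximum of ≈8.007 while both sit below 8).
A second, non-terminal event on dS/dt records every local maximum of S —
those are transversal sign changes of the event function and cannot be
missed.  Whenever the earliest S-maximum at or above S_T precedes any
detected crossing, the true first crossing is recovered from the dense
output by bisection.  Without this safeguard the unstable order-1 orbit
of the bistable regime is undetectable.

**Convergence detection.**  When an orbit is captured by an interior
attractor with S* < S_T it never pulses again; the driver integrates in
windows of length 10/(d+θ) and terminates with status `"converged"` when
the windowed maximum of S stops increasing.  The Poincaré map instead
uses a hard no-return timeout of 50/(d+θ) and raises `NoReturnError`.

Initial states with S₀ > S_T are rejected rather than pulsed
immediately (the model leaves that case unspecified; rejection is the
conservative reading).

## Disease-free periodic orbit and its multiplier

With I = 0 the susceptible pool follows dS/dt = (d+θ)(A/d − S), giving
the closed-form sawtooth ξ(t), period T = ln(Δ₁)/(d+θ) and jump factor
Δ₁ = (A−d(1−q)S_T)/(A−dS_T) > 1.  The Floquet multiplier of the orbit
against infection is

    μ₂ = Δ₁^E · exp(−βqS_T/(d+θ)),   E = (βA/d − d − v − c/b)/(d+θ),

computed from the closed form; a second code path rebuilds it as
Δ₁ · exp(∫₀ᵀ divergence dt) by quadrature and must agree to 1e-12.  The
identity βA/d − d − v − c/b = (d+v+c/b)(R₀−1) ties the sign of E to R₀,
so R₀ < 1 forces μ₂ < 1 (stable orbit).  A third, fully independent
route — the finite-difference slope of the numerical Poincaré map at
I₀ = 0 — agrees with the closed form to 1e-4 relative on the presets and
a seeded random parameter grid (tests).

## Poincaré map, derivatives, fixed points

P₁ maps the infected coordinate of a post-pulse point ((1−q)S_T, I₀) to
the infected coordinate at the next threshold crossing; P₁(0) = 0 is
returned analytically.  The admissible I₀ range is bounded by tangency
heights, the positive roots of B I² + (D+Bb+c) I + Db = 0 with
B = v − θ − βS₀ and D = (d+θ)(A/d − S₀) on the section S = S₀ (unique
positive root iff B < 0, taken on the negative branch of the quadratic
formula).  For the globally-stable cases the range is closed by forward
continuation of the post-pulse tangency orbit; for the bistable case
(stable endemic point with S* < S_T) by backward continuation of the
threshold tangency.  For the complex cases (unstable endemic point or
backward-bifurcation window) no a-priori range is computed: the map is
still evaluated pointwise and failures surface as errors.

Derivatives of P₁ use Richardson-extrapolated finite differences:
one-sided stencils anchored at P₁(0) = 0 at the origin, central stencils
in the interior.  Step sizes grow with the order (1e-4, 1e-2, 5e-2):
the higher orders divide by h², h³ and must stay above integrator noise,
and the stencil integrations run at tightened tolerance (rtol 1e-11,
atol 1e-15) because for small multipliers P₁(h) itself is tiny.  The
second derivative has an independent quadrature route,
g″(0) = μ₂ ∫ m(s) ∂I(s,0)/∂I₀ ds over the inter-section strip, with
m(s) the second I-derivative of the slope field F₂/F₁ along I = 0
(verified symbolically against sympy); the two routes agree to ~1e-2
relative.  The analogous printed integrand for the third derivative is
internally inconsistent (it fails the same symbolic check), so g‴(0) is
computed only by finite differences and the printed form is kept,
unused, as `_n_of_s_printed`.

Fixed points are located by a sign scan of P₁(I) − I on a grid over the
admissible range, truncated at the first non-returning point, followed
by Brent refinement; each root carries the numeric multiplier dP₁/dI₀.
A fixed point is an order-1 periodic orbit of the hybrid system; the
tests close the loop by simulating one pulse cycle from the fixed point
and recovering it to 1e-6.

## Critical parameters and bifurcation type

The disease-free orbit changes stability where μ₂(α) = 1 for a control
parameter α ∈ {q, S_T, A}.  Closed-form partials of μ₂ (each verified
against central finite differences to 1e-6 relative) give the
monotonicity structure used for bracketing:

- **q**: μ₂(q) rises on (0, q̃) and falls on (q̃, 1), with
  q̃ = 1 − (b(d+v)+c)/(bβS_T) when that lies in (0,1); a root q₁* exists
  in (q̃, 1) iff μ₂|_{q=1} < 1.
- **S_T**: the turning point solves βd(1−q)S̄² + βA(q−2)S̄ + A(d+v+c/b) = 0,
  real whenever R₀ > K(q) = 4(1−q)/(q−2)² (and K < 1 on (0,1), so R₀ > 1
  suffices); μ₂ dips below 1 at the lower root S̄₁ and diverges as
  S_T → (A/d)⁻, so S_T* ∈ (S̄₁, A/d) is unique.
- **A**: μ₂ diverges as A → (dS_T)⁺ when βS_T > d+v+c/b and tends to 1 as
  A → ∞ with ln μ₂ ~ C/A, C = dqS_T(β(2−q)S_T/2 − d−v−c/b)/(d+θ).  (A
  commonly quoted finite limit exp(−βqS_T/(d+θ)) is incorrect: the
  exponent of Δ₁ grows ∝ A while ln Δ₁ decays ∝ 1/A, and their product
  cancels that factor exactly.)  For C < 0 the doubling bracket always
  closes; otherwise no crossing may exist and the solver raises.

All roots are refined to |μ₂ − 1| < 1e-8 (brentq).  At a critical point
the map family is classified by the standard one-parameter-map criteria:
|g″(0)| > 1e-4 ⇒ transcritical; g″(0) ≈ 0 with |g‴(0)| > 1e-4 ⇒
supercritical pitchfork; both below the noise floor ⇒ `inconclusive`
(below combined quadrature + finite-difference noise the sign of g″ is
not trustworthy, and an honest "don't know" beats a coin flip).  For the
baseline family all three critical points are transcritical with
g″(0) ≈ 3.3–3.8 > 0, and the cross-derivative ∂²P₁/∂I₀∂α = ∂μ₂/∂α is
negative at q₁* and A*, positive at S_T*.

## Numerical choices, degenerate inputs, limitations

- All computations are deterministic; there is no randomness anywhere in
  the library (the test suite seeds its own parameter-grid generator).
- Boundary tolerance for case labels: 1e-9 (relative where scaled).
- Root refinement: brentq xtol 1e-12 (scaled for the A-root).
- CSV output uses 12 significant digits and '#'-comment headers so
  independent implementations can be diffed.
- The impulse-count invariant is exact except when a pulse coincides
  with the integration horizon to within floating rounding; tests avoid
  placing the horizon exactly on a pulse.
- Not covered: order-k (k ≥ 2) periodic orbits, rigorous admissible-range
  construction for the complex phase portraits (cases with an unstable
  endemic point or a backward-bifurcation window), numerical
  continuation of the positive-orbit branch beyond grid scans, and any
  form of stochasticity or time-varying parameters.

## What the presets emulate

The three presets are stated parameter regimes, not fits to data: `fig1`
sits just past the instability threshold of the disease-free orbit
(μ₂ ≈ 1.0095), `fig2a` is the elimination regime (threshold below the
endemic S*, disease-free orbit globally attracting), `fig2b` the
bistable regime (stable disease-free orbit, stable endemic point,
unstable order-1 orbit between).  A green test establishes that the
package reproduces the analytic structure of these regimes — multiplier
values, equilibrium locations, fixed-point counts and bifurcation
types — not that the parameterisation describes any real epidemic.
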