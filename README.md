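# sispulse

Simulation and bifurcation analysis of an **SIS epidemic model with
saturated treatment under susceptible-threshold pulse vaccination** — a
state-dependent impulsive (hybrid) dynamical system.

## The model

Between interventions the susceptible/infected pair follows the planar
system (the total population is held at its demographic equilibrium
N = A/d, which folds the vaccinated compartment in):

    dS/dt = A - dS - βSI + vI + θ(A/d - S - I) + cI/(b+I)
    dI/dt = βSI - (d+v)I - cI/(b+I)

with recruitment A, natural mortality d, transmission β, spontaneous
recovery v, vaccine waning θ and a saturating treatment term cI/(b+I)
(capacity c, half-saturation b).  The control layer is *state-dependent*:
whenever the susceptible pool grows back to a threshold S_T, a fraction q
of susceptibles is vaccinated in one pulse,

    S ↦ (1-q) S_T,   I ↦ I        (when S reaches S_T).

Key quantities the package computes:

- **R₀ = Abβ / (d(c + b(d+v)))** and the backward-bifurcation thresholds
  A₁, R̂₀ of the ODE core; endemic equilibria are roots of
  I² + a₁I + a₂ = 0 and their stability follows the trace index
  H(I) = θ + d + βI − cI/(b+I)².
- The **disease-free periodic orbit** (ξ(t), 0): a sawtooth with period
  T = ln[(A−d(1−q)S_T)/(A−dS_T)]/(d+θ) and Floquet multiplier

      μ₂ = Δ₁^((βA/d − d − v − c/b)/(d+θ)) · exp(−βqS_T/(d+θ)),

  Δ₁ = (A−d(1−q)S_T)/(A−dS_T); the orbit is orbitally stable iff μ₂ < 1.
- The **Poincaré map** P₁ on the post-pulse section S = (1−q)S_T,
  evaluated by event-driven integration (with a grazing-safe event
  scheme); its positive fixed points are order-1 periodic orbits, and
  P₁′(0) = μ₂.
- **Critical parameter values** q₁*, S_T*, A* where μ₂ = 1, and the
  transcritical-vs-pitchfork classification from g″(0)/g‴(0) of the map.

## Worked example

The preset `fig2b` (β=0.8, A=7, d=0.7, v=4, θ=0.1, c=2.5, b=1, q=0.22,
S_T=8) is the bistable configuration:

```
$ sispulse floquet --preset fig2b
T=0.789089721052
Delta1=1.88
mu2=0.323444343987
stable=True
globally_stable=False
case=C2
```

μ₂ ≈ 0.32 < 1: the disease-free pulsed orbit is orbitally stable.  Yet
the ODE core still has a stable endemic state:

```
$ sispulse equilibria --preset fig2b
R0=1.11111111111
...
S=6.58239724004
I=3.41760275996
H=3.09626959487
stability=stable node
```

The two attractors are separated by an unstable order-1 periodic orbit —
the positive fixed point of the Poincaré map:

```
$ sispulse poincare --preset fig2b
I_fix=1.15488430036
multiplier=15.089645487
stable=False
```

Orbits pulsed back with fewer than ≈1.155 infecteds on the section are
driven to elimination; above it, the epidemic settles at the endemic
state.  For the β=1 baseline (`fig1`, μ₂ ≈ 1.0095 just above 1), the
critical threshold where the disease-free orbit changes stability is

```
$ sispulse bifurcate --preset fig1 --wrt S_T
parameter=S_T
critical_value=7.98730287749
mu2_cross_slope=1
g2=3.72346252629
bif_type=transcritical
```

i.e. lowering the vaccination trigger S_T below ≈7.987 stabilises the
disease-free orbit, losing stability transcritically (g″(0) > 0) as the
threshold is raised through it.  The same machinery handles the pulse
fraction `--wrt q` and the recruitment rate `--wrt A`, plus 1- and
2-parameter sweeps via `sispulse scan`.

As a library:

```python
from sispulse import get_preset, floquet_mu2, find_fixed_points, simulate

p = get_preset("fig2b")
floquet_mu2(p)                     # 0.3234443439873353
[fp.I_fix for fp in find_fixed_points(p)]   # [1.154884300364961]
traj = simulate(p, (6.24, 0.5), horizon=50)
traj.to_frame()                    # t, S, I, segment_index, is_impulse
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-evaluates, through the package's closed-form code paths at the
baseline parameter set, the limit identities of the Floquet multiplier
(μ₂ as q → 0⁺ and as S_T → 0⁺) and of the threshold-bifurcation
auxiliary function K(q) at q = 0, writing one JSON object per target.
All quantities are deterministic; the seed argument is accepted for
interface uniformity.
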