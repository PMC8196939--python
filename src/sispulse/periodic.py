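"""The disease-free (semi-trivial) periodic orbit and its Floquet multiplier.

With I = 0 the susceptible pool obeys dS/dt = (d+theta)(A/d - S) below the
threshold and is reset to (1-q) S_T when it reaches S_T, producing the
periodic sawtooth

    xi(t) = A/d - (A/d - (1-q) S_T) exp(-(d+theta) t),   0 < t <= T,

with period T = ln(Delta1)/(d+theta), where
Delta1 = (A - d(1-q)S_T)/(A - d S_T) > 1 is the jump factor contributed by
the pulse.  Orbital stability against infection is governed by the Floquet
multiplier

    mu2 = Delta1^((beta*A/d - d - v - c/b)/(d+theta)) * exp(-beta*q*S_T/(d+theta)),

which also equals the slope at zero of the threshold-to-threshold Poincare
map of the infected coordinate; |mu2| < 1 gives orbital asymptotic
stability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.integrate import quad

from .model_core import classify_case, compute_R0
from .params import ModelParams

__all__ = [
    "SemiTrivialSolution",
    "period_T",
    "delta1",
    "xi_eval",
    "floquet_mu2",
    "mu2_closed_form",
    "semitrivial_stability",
]


def mu2_closed_form(
    A: float, d: float, beta: float, v: float, theta: float,
    c: float, b: float, q: float, S_T: float,
) -> float:
    """Closed-form mu2 from raw parameter values.

    Unlike :func:`floquet_mu2` this entry point accepts the degenerate
    limits q = 0 and S_T = 0 (both give mu2 = 1) that fall outside the
    ``ModelParams`` invariants; it is used for limit evaluation and by the
    bifurcation scans.  Requires S_T < A/d.
    """
    if not S_T < A / d:
        raise ValueError(f"S_T = {S_T} must be below A/d = {A / d}")
    if S_T == 0 or q == 0:
        return 1.0
    ratio = (A - d * (1 - q) * S_T) / (A - d * S_T)
    expo = (beta * A / d - d - v - c / b) / (d + theta)
    try:
        return ratio**expo * math.exp(-beta * q * S_T / (d + theta))
    except OverflowError:
        return math.inf


def period_T(p: ModelParams) -> float:
    """Inter-pulse period of the disease-free orbit (beta-free)."""
    return math.log(delta1(p)) / (p.d + p.theta)


def delta1(p: ModelParams) -> float:
    """Pulse jump factor Delta1 = (A - d(1-q)S_T)/(A - d S_T) > 1."""
    return (p.A - p.d * (1 - p.q) * p.S_T) / (p.A - p.d * p.S_T)


def xi_eval(t: float, p: ModelParams) -> float:
    """Susceptible coordinate xi(t) of the disease-free orbit.

    ``t`` is reduced modulo the period T; the orbit is taken
    right-continuous at 0, so xi(0) = (1-q) S_T and xi(T) = S_T.
    """
    T = period_T(p)
    tau = t % T
    if tau == 0.0 and t > 0:
        tau = T
    level = p.A / p.d
    return level - (level - (1 - p.q) * p.S_T) * math.exp(-(p.d + p.theta) * tau)


def floquet_mu2(p: ModelParams, route: str = "closed") -> float:
    """Floquet multiplier mu2 of the disease-free periodic orbit.

    ``route="closed"`` evaluates the closed form; ``route="decomposed"``
    rebuilds mu2 as Delta1 * exp(integral of the divergence-like term
    along the orbit), evaluated by quadrature.  The two agree to ~1e-12
    and the second exists purely as an internal cross-check.
    """
    if route == "closed":
        return mu2_closed_form(p.A, p.d, p.beta, p.v, p.theta, p.c, p.b, p.q, p.S_T)
    if route == "decomposed":
        T = period_T(p)

        def integrand(t):
            # dP/dS + dQ/dI along (xi(t), 0)
            return -2 * p.d - p.theta - p.v - p.c / p.b + p.beta * xi_eval(t, p)

        val, _ = quad(integrand, 0.0, T, epsabs=1e-14, epsrel=1e-13)
        return delta1(p) * math.exp(val)
    raise ValueError(f"unknown route {route!r}")


@dataclass(frozen=True)
class SemiTrivialSolution:
    """Summary of the disease-free periodic orbit for one parameter set."""

    T: float
    Delta1: float
    mu2: float
    stable: bool
    globally_stable: bool  # case C1: every orbit approaches it
    case: str


def semitrivial_stability(p: ModelParams) -> SemiTrivialSolution:
    """Stability verdict for the disease-free periodic orbit.

    The orbit is orbitally asymptotically stable iff mu2 < 1; in
    particular R0 < 1 forces mu2 < 1.  In case C1 (no endemic state) it
    is globally attracting.
    """
    mu2 = floquet_mu2(p)
    case = classify_case(p)
    return SemiTrivialSolution(
        T=period_T(p),
        Delta1=delta1(p),
        mu2=mu2,
        stable=mu2 < 1,
        globally_stable=(case == "C1"),
        case=case,
    )


def _exponent(p: ModelParams) -> float:
    """Exponent of Delta1 in mu2; negative iff R0 < 1 since
    beta*A/d - d - v - c/b = (d + v + c/b)(R0 - 1)."""
    return (p.beta * p.A / p.d - p.d - p.v - p.c / p.b) / (p.d + p.theta)


# re-export for tests of the sign identity
exponent_identity_residual = lambda p: _exponent(p) * (p.d + p.theta) - (
    (p.d + p.v + p.c / p.b) * (compute_R0(p) - 1)
)
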