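"""Numerical Poincare map of the pulsed system and its fixed points.

The map P1 sends the infected coordinate I0 of a post-pulse point
((1-q)S_T, I0) to the infected coordinate of the orbit's next crossing of
the threshold line S = S_T.  Fixed points of P1 are order-1 periodic
orbits of the hybrid system; the trivial fixed point I = 0 is the
disease-free periodic orbit and the slope of P1 there equals its Floquet
multiplier mu2.

The admissible range of I0 is bounded by tangency points of the vector
field with the two sections: on a vertical line S = S0 the field is
tangent (dS/dt = 0) at the positive root of

    B I^2 + (D + B b + c) I + D b = 0,
    B = v - theta - beta*S0,   D = (d+theta)(A/d - S0),

which has a unique positive root iff B < 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model_core import _rhs, classify_case, endemic_equilibria
from .params import ModelParams

__all__ = [
    "NoReturnError",
    "PoincareDomain",
    "FixedPoint",
    "tangency_height",
    "build_domain",
    "map_P1",
    "derivative_P1",
    "find_fixed_points",
]

#: factor for the no-return timeout, in units of 1/(d+theta)
NO_RETURN_FACTOR = 50.0
RTOL = 1e-10
ATOL = 1e-12


class NoReturnError(RuntimeError):
    """Orbit failed to reach the threshold section S = S_T."""


def tangency_height(S0: float, p: ModelParams) -> float | None:
    """Height I > 0 where the vector field is tangent to the line S = S0.

    Returns None when the coefficient B = v - theta - beta*S0 is
    nonnegative (no positive root).  Uses the negative branch of the
    quadratic formula; with B < 0, D > 0 this is the unique positive root.
    """
    B = p.v - p.theta - p.beta * S0
    D = (p.d + p.theta) * (p.A / p.d - S0)
    if B >= 0:
        return None
    mid = D + B * p.b + p.c
    disc = mid * mid - 4 * B * D * p.b
    return (-mid - math.sqrt(disc)) / (2 * B)


@dataclass
class PoincareDomain:
    """Sections, tangency heights and admissible I0 range of the map.

    ``I_qST``/``I_ST`` are the tangency heights on the post-pulse section
    S = (1-q)S_T and on the threshold section S = S_T (None when the
    respective B-coefficient is nonnegative).  ``I_impulse_max`` bounds
    the impulsive set {S = S_T, 0 <= I <= I_impulse_max}; ``I_max`` is
    the least upper bound of I0 values guaranteed to return to S = S_T
    (None when unknown, cases C3/C4).
    """

    case: str
    B: float
    D: float
    B1: float
    D1: float
    I_qST: float | None = None
    I_ST: float | None = None
    I_impulse_max: float | None = None
    I_max: float | None = None
    notes: list[str] = field(default_factory=list)


def _integrate_to_threshold(I0: float, p: ModelParams, rtol=RTOL, atol=ATOL):
    """Run the orbit from ((1-q)S_T, I0) to its first crossing of S = S_T.

    Returns (crossing time, I at crossing).  Raises NoReturnError after
    the timeout 50/(d+theta) without an upward crossing.  Grazing
    passages near the threshold tangency are handled by
    :func:`~sispulse.hybrid.advance_to_threshold`.
    """
    from .hybrid import advance_to_threshold

    def rhs(t, y):
        return _rhs(y[0], y[1], p)

    t_max = NO_RETURN_FACTOR / (p.d + p.theta)
    _, _, t_hit, y_hit = advance_to_threshold(
        rhs, 0.0, [(1 - p.q) * p.S_T, I0], t_max, p, rtol=rtol, atol=atol)
    if t_hit is None:
        raise NoReturnError(
            f"orbit from I0={I0} did not reach S=S_T within t={t_max:.3g}")
    return t_hit, float(y_hit[1])


def _continue_orbit_to_section(start, p: ModelParams, S_target: float, backward: bool):
    """Integrate the smooth flow from ``start`` until S = S_target.

    Used for the tangency orbits: forward continuation of the post-pulse
    tangency to the threshold, and backward continuation of the threshold
    tangency to the post-pulse section.  Returns the I value at the
    section, or None if it is not reached before the timeout.
    """
    sign = -1.0 if backward else 1.0

    def rhs(t, y):
        dS, dI = _rhs(y[0], y[1], p)
        return (sign * dS, sign * dI)

    def hit(t, y):
        return y[0] - S_target

    hit.terminal = True
    hit.direction = 0.0

    t_max = NO_RETURN_FACTOR / (p.d + p.theta)
    sol = solve_ivp(rhs, (0.0, t_max), list(start), method="DOP853",
                    rtol=RTOL, atol=ATOL, events=hit)
    if not sol.t_events[0].size:
        return None
    return float(sol.y_events[0][0][1])


def build_domain(p: ModelParams) -> PoincareDomain:
    """Construct sections, tangencies and the admissible I0 range.

    Case C1 (and C2 with S_T < S*): the field is tangent to the
    post-pulse section at I_qST; the forward continuation of that orbit
    meets the threshold at I_impulse_max, bounding both the impulsive set
    and the returning I0 range.  Case C2 with S_T > S*: the tangency sits
    on the threshold section at I_ST and its backward continuation to the
    post-pulse section yields I_max.  Cases C3/C4: the phase portrait is
    too involved for an a-priori domain; I_max is None with a warning.
    """
    case = classify_case(p)
    S_phase = (1 - p.q) * p.S_T
    B = p.v - p.theta - p.beta * S_phase
    D = (p.d + p.theta) * (p.A / p.d - S_phase)
    B1 = p.v - p.theta - p.beta * p.S_T
    D1 = (p.d + p.theta) * (p.A / p.d - p.S_T)
    dom = PoincareDomain(case=case, B=B, D=D, B1=B1, D1=D1,
                         I_qST=tangency_height(S_phase, p),
                         I_ST=tangency_height(p.S_T, p))

    if case in ("C3", "C4"):
        dom.notes.append(f"case {case}: admissible range not computed a priori")
        warnings.warn(dom.notes[-1], stacklevel=2)
        return dom

    S_star = None
    if case == "C2":
        rep = endemic_equilibria(p)
        if rep.endemics:
            S_star = rep.endemics[-1].S

    c1_like = case in ("C1", "boundary") or (S_star is not None and p.S_T < S_star)
    if c1_like:
        if dom.I_qST is not None and dom.I_qST < p.A / p.d - S_phase:
            dom.I_impulse_max = _continue_orbit_to_section(
                (S_phase, dom.I_qST), p, p.S_T, backward=False)
            dom.I_max = dom.I_impulse_max
        else:
            # tangency absent or outside D: every admissible I0 returns
            dom.I_max = p.A / p.d - S_phase
            dom.notes.append("post-pulse tangency outside D; range bounded by D")
    else:  # C2 with S_T > S*
        if dom.I_ST is not None:
            dom.I_impulse_max = dom.I_ST
            dom.I_max = _continue_orbit_to_section(
                (p.S_T, dom.I_ST), p, S_phase, backward=True)
            if dom.I_max is None:
                dom.notes.append("backward continuation of threshold tangency "
                                 "did not reach the post-pulse section")
                warnings.warn(dom.notes[-1], stacklevel=2)
        else:
            dom.notes.append("B1 >= 0: no threshold tangency; range unknown")
            warnings.warn(dom.notes[-1], stacklevel=2)
    return dom


def map_P1(I0: float, p: ModelParams, rtol: float = RTOL, atol: float = ATOL) -> float:
    """Poincare map: next threshold-crossing height of the orbit from
    ((1-q)S_T, I0).

    P1(0) = 0 is returned analytically (the I = 0 manifold is invariant).
    Raises ``ValueError`` for negative I0 and :class:`NoReturnError` when
    the orbit fails to reach S = S_T (e.g. attracted to the endemic
    state) within 50/(d+theta) time units.
    """
    if I0 < 0:
        raise ValueError(f"I0 must be nonnegative, got {I0}")
    if I0 == 0:
        return 0.0
    return _integrate_to_threshold(I0, p, rtol=rtol, atol=atol)[1]


def return_time(I0: float, p: ModelParams) -> float:
    """Time for the orbit from ((1-q)S_T, I0) to reach S = S_T."""
    if I0 == 0:
        from .periodic import period_T

        return period_T(p)
    return _integrate_to_threshold(I0, p)[0]


# Finite-difference steps per derivative order; the higher orders divide
# by h^2, h^3 so they need larger steps to stay above integrator noise
_DEFAULT_H = {1: 1e-4, 2: 1e-2, 3: 5e-2}


def derivative_P1(I0: float, p: ModelParams, order: int = 1, h: float | None = None) -> float:
    """Finite-difference derivative of P1 at I0 (order 1, 2 or 3).

    Uses one-sided stencils anchored at the analytic value P1(0) = 0 when
    I0 = 0 (the map is not defined for negative I0) and central stencils
    in the interior, both with one step of Richardson extrapolation.  The
    order-1 value at I0 = 0 reproduces the closed-form Floquet multiplier
    to ~1e-6 relative.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    if h is None:
        h = _DEFAULT_H[order] * max(1.0, I0)

    # tighter-than-default integration: differences of nearly equal P1
    # values divide by h^order, and for small multipliers P1(h) itself is
    # tiny, so the integration error must sit well below atol*h
    P = lambda x: map_P1(x, p, rtol=1e-11, atol=1e-15)

    if I0 == 0:
        if order == 1:
            D = lambda s: P(s) / s
        elif order == 2:
            D = lambda s: (P(2 * s) - 2 * P(s)) / s**2
        else:
            D = lambda s: (P(3 * s) - 3 * P(2 * s) + 3 * P(s)) / s**3
        return 2 * D(h / 2) - D(h)

    reach = 2 if order == 3 else 1  # widest stencil offset in units of h
    if I0 - reach * h < 0:
        h = I0 / (2 * reach)  # shrink so the stencil stays in I >= 0

    if order == 1:
        D = lambda s: (P(I0 + s) - P(I0 - s)) / (2 * s)
        return (4 * D(h / 2) - D(h)) / 3
    if order == 2:
        D = lambda s: (P(I0 + s) - 2 * P(I0) + P(I0 - s)) / s**2
        return (4 * D(h / 2) - D(h)) / 3
    D = lambda s: (P(I0 + 2 * s) - 2 * P(I0 + s) + 2 * P(I0 - s) - P(I0 - 2 * s)) / (2 * s**3)
    return (4 * D(h / 2) - D(h)) / 3


@dataclass(frozen=True)
class FixedPoint:
    """Positive fixed point of P1 = order-1 periodic orbit of the system."""

    I_fix: float
    multiplier: float
    stable: bool


def find_fixed_points(
    p: ModelParams,
    grid_size: int = 60,
    I_hi: float | None = None,
    refine_tol: float = 1e-10,
) -> list[FixedPoint]:
    """Locate positive fixed points of P1 by sign scan + bisection.

    Scans P1(I) - I on a grid over (0, I_hi]; ``I_hi`` defaults to the
    admissible range from :func:`build_domain` (required to be finite
    when not supplied).  Grid points where the orbit does not return are
    recorded and skipped with a warning.  Each sign-change bracket is
    refined by Brent's method and the multiplier is the numeric
    dP1/dI0 at the root.  The trivial fixed point I = 0 (the disease-free
    orbit) is not included.
    """
    if I_hi is None:
        dom = build_domain(p)
        if dom.I_max is None:
            raise ValueError(
                "admissible range unknown (case C3/C4); supply I_hi explicitly")
        I_hi = dom.I_max * (1 - 1e-9)

    f = lambda I: map_P1(I, p) - I
    # contiguous scan from just above 0 (where sign(P1 - I) = sign(mu2 - 1));
    # stop at the first non-returning grid point: beyond it the orbit is
    # captured by the endemic attractor and the map is undefined
    grid = np.concatenate(([I_hi / grid_size / 100], np.linspace(I_hi / grid_size, I_hi, grid_size)))
    pts: list[tuple[float, float]] = []
    for I in grid:
        try:
            pts.append((I, f(I)))
        except NoReturnError:
            warnings.warn(
                f"grid point I0={I:.6g} did not return to the threshold; "
                "scan truncated there", stacklevel=2)
            break

    roots: list[float] = []
    for (Ia, va), (Ib, vb) in zip(pts[:-1], pts[1:]):
        if va * vb < 0:
            roots.append(brentq(f, Ia, Ib, xtol=refine_tol))

    out = []
    for r in roots:
        mult = derivative_P1(r, p, order=1, h=min(1e-4 * max(1.0, r), r / 4))
        out.append(FixedPoint(I_fix=r, multiplier=mult, stable=abs(mult) < 1))
    return out
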