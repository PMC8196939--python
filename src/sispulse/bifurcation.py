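"""Critical parameter values where mu2 = 1 and bifurcation classification.

The disease-free periodic orbit loses orbital stability where its Floquet
multiplier mu2 crosses 1.  This module locates those critical values in
the pulse fraction q, the threshold S_T and the recruitment rate A,
computes the second/third derivatives of the Poincare map at the trivial
fixed point, and classifies the bifurcation (transcritical vs supercritical
pitchfork) from the standard one-parameter-map criteria: a nonzero g''(0)
gives a transcritical exchange of stability; g''(0) = 0 with g'''(0) != 0
gives a pitchfork.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from .params import ModelParams
from .periodic import floquet_mu2, mu2_closed_form
from .model_core import compute_R0

__all__ = [
    "BifurcationResult",
    "mu2_of",
    "mu2_partial",
    "q_tilde",
    "K_of_q",
    "ST_bar_roots",
    "critical_q",
    "critical_ST",
    "critical_A",
    "g_second_zero",
    "classify_bifurcation",
    "scan",
    "scan2d",
]

#: |g2| below this multiple of mu2 is treated as numerically zero when
#: deciding transcritical vs pitchfork (combined quadrature + FD noise floor)
TOL_G = 1e-4
ROOT_TOL = 1e-12


@dataclass
class BifurcationResult:
    """Critical point of the semi-trivial orbit in one parameter."""

    parameter: str  # "q" | "S_T" | "A"
    critical_value: float | None
    mu2_cross_slope: int | None = None  # sign of d(mu2)/d(alpha) at the critical point
    g2: float | None = None
    g3: float | None = None
    bif_type: str | None = None  # "transcritical" | "pitchfork" | "inconclusive"
    existence_case: str = ""
    diagnostics: dict | None = None


def mu2_of(p: ModelParams, wrt: str, value: float) -> float:
    """Closed-form mu2 with one parameter overridden (no invariant checks
    beyond S_T < A/d, so scans may cross q = 0 or S_T = 0 limits)."""
    kw = p.as_dict()
    if wrt not in kw:
        raise ValueError(f"unknown parameter {wrt!r}")
    kw[wrt] = value
    return mu2_closed_form(**kw)


def mu2_partial(p: ModelParams, wrt: str) -> float:
    """Closed-form partial derivative of mu2 in q, S_T or A."""
    mu2 = floquet_mu2(p)
    dth = p.d + p.theta
    sat = p.d + p.v + p.c / p.b  # combined removal rate d + v + c/b
    if wrt == "q":
        num = mu2 * p.d * p.S_T * (p.beta * (1 - p.q) * p.S_T - sat)
        return num / (dth * (p.A - p.d * (1 - p.q) * p.S_T))
    if wrt == "S_T":
        f = (p.d * p.A * (p.beta * p.A / p.d - sat)
             / ((p.A - p.d * p.S_T) * (p.A - p.d * (1 - p.q) * p.S_T))) - p.beta
        return p.q * mu2 / dth * f
    if wrt == "A":
        B1 = _B1_of_A(p, p.A)
        return p.beta * mu2 / dth * B1
    raise ValueError(f"unknown parameter {wrt!r}")


def q_tilde(p: ModelParams, paper_literal: bool = False) -> float | None:
    """Turning point of mu2(q): q~ = 1 - (b(d+v)+c)/(b*beta*S_T).

    mu2(q) increases on (0, q~) and decreases on (q~, 1).  Returns None
    when S_T <= (b(d+v)+c)/(b*beta) (then mu2 is decreasing on all of
    (0,1)).  ``paper_literal=True`` uses b(b+v)+c in place of b(d+v)+c,
    a variant sometimes quoted; the default follows the sign factor
    beta*(1-q)*S_T - d - v - c/b of d(mu2)/dq.
    """
    num = p.b * (p.b + p.v) + p.c if paper_literal else p.b * (p.d + p.v) + p.c
    qt = 1 - num / (p.b * p.beta * p.S_T)
    return qt if 0 < qt < 1 else None


def K_of_q(q: float) -> float:
    """K(q) = 4(1-q)/(q-2)^2; the discriminant of the S_T-turning-point
    quadratic is positive iff R0 > K(q).  K(0) = 1 and K decreases on
    (0, 1), so R0 > 1 always suffices."""
    return 4 * (1 - q) / (q - 2) ** 2


def ST_bar_roots(p: ModelParams) -> tuple[float, float]:
    """Roots ST_bar1 < A/d < ST_bar2 of the turning-point quadratic

        beta*d*(1-q)*S^2 + beta*A*(q-2)*S + A*(d+v+c/b) = 0,

    where d(mu2)/dS_T changes sign.  Requires a positive discriminant,
    i.e. R0 > K(q); guaranteed when R0 > 1."""
    R0 = compute_R0(p)
    disc = (p.q - 2) ** 2 - 4 * (1 - p.q) / R0
    if disc <= 0:
        raise ValueError(f"discriminant nonpositive: R0 = {R0} <= K(q) = {K_of_q(p.q)}")
    lvl = p.A / p.d
    s = math.sqrt(disc)
    lo = lvl * (-(p.q - 2) - s) / (2 * (1 - p.q))
    hi = lvl * (-(p.q - 2) + s) / (2 * (1 - p.q))
    return lo, hi


def critical_q(p: ModelParams, paper_literal: bool = False) -> BifurcationResult:
    """Critical pulse fraction q1* in (q~, 1) with mu2(q1*) = 1, if any.

    Existence branches (the q-value stored in ``p`` is ignored):
    no root when S_T <= (b(d+v)+c)/(b*beta) (mu2 decreasing on (0,1));
    no root when mu2|q=1 >= 1; otherwise a unique root in (q~, 1).
    ``paper_literal`` uses the printed q~ variant (exploration only).
    """
    qt = q_tilde(p, paper_literal=paper_literal)
    if qt is None:
        return BifurcationResult("q", None,
                                 existence_case="mu2 decreasing on (0,1): S_T <= (b(d+v)+c)/(b beta)")
    mu2_at_1 = mu2_of(p, "q", 1.0)
    if mu2_at_1 >= 1:
        return BifurcationResult("q", None,
                                 existence_case="mu2|q=1 >= 1: semi-trivial orbit unstable for all q",
                                 diagnostics={"q_tilde": qt, "mu2_at_q1": mu2_at_1})
    f = lambda q: mu2_of(p, "q", q) - 1
    root = brentq(f, qt, 1.0 - 1e-14, xtol=ROOT_TOL)
    return _finalize(p, "q", root, extra={"q_tilde": qt, "mu2_at_q1": mu2_at_1},
                     existence_case="unique root in (q_tilde, 1)")


def critical_ST(p: ModelParams) -> BifurcationResult:
    """Critical threshold S_T* in (ST_bar1, A/d) with mu2(S_T*) = 1.

    Requires R0 > 1 (then the turning-point quadratic has real roots,
    mu2 dips below 1 at ST_bar1 and diverges as S_T -> (A/d)-, so the
    root exists and is unique).
    """
    R0 = compute_R0(p)
    if R0 <= 1:
        raise ValueError(f"critical_ST requires R0 > 1, got R0 = {R0}")
    lo, hi = ST_bar_roots(p)
    lvl = p.A / p.d
    f = lambda s: mu2_of(p, "S_T", s) - 1
    # mu2(ST_bar1) < 1; walk toward A/d until mu2 > 1 to bracket
    upper = lvl - (lvl - lo) * 1e-3
    while f(upper) < 0:
        upper = lvl - (lvl - upper) * 1e-3
    root = brentq(f, lo, upper, xtol=ROOT_TOL)
    return _finalize(p, "S_T", root,
                     extra={"ST_bar1": lo, "ST_bar2": hi, "K_q": K_of_q(p.q)},
                     existence_case="unique root in (ST_bar1, A/d)")


def _B1_of_A(p: ModelParams, A: float, paper_literal: bool = False) -> float:
    """Slope factor of d(mu2)/dA: d(mu2)/dA = beta*mu2/(d+theta) * B1(A).

    Derived by differentiating ln(mu2) in A:

        B1(A) = ln(Delta1)/d - (A/d - (d+v+c/b)/beta) * d*q*S_T
                               / ((A - d(1-q)S_T)(A - d S_T)).

    ``paper_literal=True`` drops the 1/d on the log term, reproducing a
    printed variant of this factor that does not match the derivative of
    the closed-form mu2 (checked against central finite differences).
    """
    sat = p.d + p.v + p.c / p.b
    num = (A / p.d - sat / p.beta) * p.d * p.q * p.S_T
    logterm = math.log((A - p.d * (1 - p.q) * p.S_T) / (A - p.d * p.S_T))
    if not paper_literal:
        logterm /= p.d
    return logterm - num / ((A - p.d * (1 - p.q) * p.S_T) * (A - p.d * p.S_T))


def _B2_of_A(p: ModelParams, A: float) -> float:
    """Curvature diagnostic: dB1/dA = q*S_T*B2(A) / ((A-a)^2 (A-b)^2)
    with a = d(1-q)S_T, b = d*S_T and (derived from the corrected B1)

        B2(A) = (d*S_T*(2-q) - 2*d*(d+v+c/b)/beta) * A
                + d^2*(d+v+c/b)*S_T*(2-q)/beta - 2*d^2*(1-q)*S_T^2.
    """
    sat = p.d + p.v + p.c / p.b
    return ((p.d * p.S_T * (2 - p.q) - 2 * p.d * sat / p.beta) * A
            + p.d**2 * sat * p.S_T * (2 - p.q) / p.beta
            - 2 * p.d**2 * (1 - p.q) * p.S_T**2)


def critical_A(p: ModelParams, A_cap: float = 1e12) -> BifurcationResult:
    """Critical recruitment A* > d*S_T with mu2(A*) = 1.

    mu2(A) diverges as A -> (d S_T)+ whenever beta*S_T > d + v + c/b, and
    tends to 1 as A -> infinity: the Delta1 exponent grows like A while
    ln Delta1 decays like 1/A, their product cancelling the
    exp(-beta q S_T/(d+theta)) factor; the residual is ln mu2 ~ C/A with
    C = d q S_T (beta(2-q)S_T/2 - d-v-c/b)/(d+theta).  When C < 0 the
    multiplier sits below 1 beyond the root, so a bracket is found by
    doubling the upper end until mu2 < 1; if no sign change appears below
    ``A_cap`` a ValueError is raised (C >= 0 regime: the disease-free
    orbit can stay unstable for all admissible A).  B1(A), B2(A) are
    reported as monotonicity diagnostics.
    """
    A_lo = p.d * p.S_T * (1 + 1e-9)
    f = lambda A: mu2_of(p, "A", A) - 1
    lo = A_lo
    if f(lo) < 0:
        # walk right until mu2 > 1; if never, there is no crossing from above
        while f(lo) < 0 and lo < A_cap:
            lo *= 2
        if lo >= A_cap:
            raise ValueError("no sign change of mu2(A) - 1 found below the cap")
        lo /= 2
    hi = max(2 * lo, 2 * p.A)
    while f(hi) > 0:
        hi *= 2
        if hi > A_cap:
            raise ValueError("no sign change of mu2(A) - 1 found below the cap")
    root = brentq(f, lo, hi, xtol=ROOT_TOL * max(1.0, hi))
    return _finalize(p, "A", root,
                     extra={"B1_at_root": _B1_of_A(p, root), "B2_at_root": _B2_of_A(p, root)},
                     existence_case="bracketed root in (d*S_T, inf)")


def _m_of_s(s: float, p: ModelParams) -> float:
    """Second I-derivative of the slope field h = F2/F1 along I = 0."""
    lvl = p.A / p.d
    dth = p.d + p.theta
    sat = p.d + p.v + p.c / p.b
    num = (2 * p.c / p.b**2 * (lvl - s) * dth
           - 2 * (p.beta * s - sat) * (-p.beta * s + p.v - p.theta + p.c / p.b))
    return num / ((lvl - s) ** 2 * dth**2)


def _dI_dI0_of_s(s: float, p: ModelParams) -> float:
    """First variation dI(s,0)/dI0 of the orbit along the I = 0 manifold."""
    dth = p.d + p.theta
    expo = (p.beta * p.A / p.d - p.d - p.v - p.c / p.b) / dth
    base = (p.A - p.d * (1 - p.q) * p.S_T) / (p.A - p.d * s)
    return base**expo * math.exp(-p.beta * (s - (1 - p.q) * p.S_T) / dth)


def g_second_zero(p: ModelParams) -> float:
    """Second derivative g''(0) of the Poincare map at the trivial fixed
    point, by adaptive quadrature of m(s) * dI(s,0)/dI0 over the
    inter-section strip ((1-q)S_T, S_T), scaled by g'(0) = mu2."""
    mu2 = floquet_mu2(p)
    val, err = quad(lambda s: _m_of_s(s, p) * _dI_dI0_of_s(s, p),
                    (1 - p.q) * p.S_T, p.S_T, epsabs=1e-12, epsrel=1e-10, limit=200)
    if err > 1e-6 * max(1.0, abs(val)):
        warnings.warn(f"g''(0) quadrature error estimate {err:.2g} is large", stacklevel=2)
    return mu2 * val


def _n_of_s_printed(s: float, p: ModelParams) -> float:
    """Third I-derivative of the slope field along I = 0, as printed in
    the source analysis.  The display appears typo-ridden (a cubed factor
    written as a square times a linear one, and a sign-ambiguous middle
    term), so this is exposed for exploration only; the package computes
    g'''(0) by finite differences of the map instead."""
    lvl = p.A / p.d
    dth = p.d + p.theta
    sat = p.d + p.v + p.c / p.b
    num = (6 * p.c / p.b**2 * (lvl - s) * dth
           * (2 * p.beta * s - 2 * p.v - p.d + p.theta - 2 * p.c / p.b)
           - 6 * p.c / p.b**3 * (lvl - s) ** 2 * dth**2
           + 6 * (p.beta * s - sat) ** 2 * (p.beta * s - sat))
    return num / ((lvl - s) ** 3 * dth**3)


def _finalize(p: ModelParams, wrt: str, root: float, extra: dict, existence_case: str) -> BifurcationResult:
    slope = mu2_partial(p.replace(**{wrt: root}), wrt)
    return BifurcationResult(
        parameter=wrt, critical_value=root,
        mu2_cross_slope=int(np.sign(slope)),
        existence_case=existence_case,
        diagnostics={**extra, "mu2_slope": slope},
    )


def classify_bifurcation(p: ModelParams, wrt: str, tol_g: float = TOL_G) -> BifurcationResult:
    """Find the critical value in ``wrt`` and classify the bifurcation.

    The map-family criteria are applied at the critical parameter point:
    |g''(0)| > tol_g  =>  transcritical; g''(0) ~ 0 with |g'''(0)| > tol_g
    =>  pitchfork; both tiny => inconclusive (below the numerical noise
    floor the sign of g'' is not trustworthy).  g'' comes from the
    quadrature route, g''' from Richardson finite differences of the map.
    """
    res = {"q": critical_q, "S_T": critical_ST, "A": critical_A}[wrt](p)
    if res.critical_value is None:
        return res
    from .poincare import derivative_P1

    p_star = p.replace(**{wrt: res.critical_value})
    res.g2 = g_second_zero(p_star)
    if abs(res.g2) > tol_g:
        res.bif_type = "transcritical"
    else:
        res.g3 = derivative_P1(0.0, p_star, order=3)
        res.bif_type = "pitchfork" if abs(res.g3) > tol_g else "inconclusive"
    return res


def scan(
    p: ModelParams,
    wrt: str,
    grid,
    with_fixed_points: bool = False,
    fp_grid_size: int = 40,
) -> pd.DataFrame:
    """One-parameter sweep of mu2 / stability (and optionally fixed points).

    Returns a table with one row per grid value: mu2 (same code path as
    :func:`floquet_mu2`), the stability verdict of the semi-trivial
    orbit, and, when requested and the parameter set is admissible, the
    positive fixed points of the Poincare map.  Per-point failures are
    recorded in the ``status`` column; the scan never aborts.
    """
    rows = []
    for val in np.asarray(grid, dtype=float):
        row = {wrt: val, "mu2": np.nan, "semi_trivial_stable": None,
               "n_fixed_points": np.nan, "fixed_points": "", "status": "ok"}
        try:
            mu2 = mu2_of(p, wrt, val)
            row["mu2"] = mu2
            row["semi_trivial_stable"] = bool(mu2 < 1)
        except (ValueError, ZeroDivisionError, OverflowError) as exc:
            row["status"] = f"mu2 failed: {exc}"
            rows.append(row)
            continue
        if with_fixed_points:
            from .poincare import find_fixed_points

            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fps = find_fixed_points(p.replace(**{wrt: val}), grid_size=fp_grid_size)
                row["n_fixed_points"] = len(fps)
                row["fixed_points"] = ";".join(
                    f"{fp.I_fix:.9g}@{fp.multiplier:.6g}" for fp in fps)
            except Exception as exc:
                row["status"] = f"fixed points failed: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def scan2d(p: ModelParams, wrt: tuple[str, str], grid1, grid2) -> pd.DataFrame:
    """Two-parameter mu2 grid in long format (for contour plots)."""
    a, b = wrt
    rows = []
    for v1 in np.asarray(grid1, dtype=float):
        kw = p.as_dict()
        kw[a] = v1
        for v2 in np.asarray(grid2, dtype=float):
            kw[b] = v2
            try:
                mu2 = mu2_closed_form(**kw)
                status = "ok"
            except (ValueError, ZeroDivisionError, OverflowError) as exc:
                mu2, status = np.nan, str(exc)
            rows.append({a: v1, b: v2, "mu2": mu2, "status": status})
    return pd.DataFrame(rows)
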