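"""Planar ODE core: vector field, equilibria, thresholds and local stability.

With the total population at its demographic equilibrium N = A/d the
three-compartment vaccinated model reduces to the planar system

    dS/dt = A - d*S - beta*S*I + v*I + theta*(A/d - S - I) + c*I/(b+I)
    dI/dt = beta*S*I - (d+v)*I - c*I/(b+I)

studied on the invariant triangle D = {S, I >= 0, S + I <= A/d}.  The
disease-free equilibrium is (A/d, 0); endemic equilibria lie on the line
S + I = A/d and their I-coordinates solve I^2 + a1*I + a2 = 0 with

    a1 = b + (d+v)/beta - A/d,      a2 = (c + b*(d+v))/beta - b*A/d.

The saturating treatment term makes a backward bifurcation possible: for
A above the recruitment threshold A1 two endemic states coexist while the
reproduction number sits between Rhat0 and 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams

__all__ = [
    "DomainError",
    "Equilibrium",
    "EquilibriumReport",
    "vector_field",
    "jacobian",
    "compute_R0",
    "thresholds",
    "H_index",
    "endemic_equilibria",
    "classify_case",
]

#: relative tolerance used to flag exact-boundary parameter sets
BOUNDARY_TOL = 1e-9


class DomainError(ValueError):
    """State outside the invariant set D = {S,I >= 0, S+I <= A/d}."""


def _rhs(S: float, I: float, p: ModelParams):
    """Right-hand side of the planar system, no domain checks (hot path)."""
    treat = p.c * I / (p.b + I)
    dS = p.A - p.d * S - p.beta * S * I + p.v * I + p.theta * (p.A / p.d - S - I) + treat
    dI = p.beta * S * I - (p.d + p.v) * I - treat
    return dS, dI


def vector_field(state, p: ModelParams, tol: float = 1e-9):
    """Evaluate (dS/dt, dI/dt) at ``state = (S, I)`` inside D.

    Raises :class:`DomainError` if S + I exceeds A/d by more than ``tol``
    or either coordinate is negative beyond ``tol``.
    """
    S, I = float(state[0]), float(state[1])
    if S < -tol or I < -tol or S + I > p.A / p.d + tol:
        raise DomainError(f"state (S={S}, I={I}) outside D (A/d = {p.A / p.d})")
    return _rhs(S, I, p)


def jacobian(S: float, I: float, p: ModelParams) -> np.ndarray:
    """Jacobian matrix of the planar vector field at (S, I)."""
    dtreat = p.c * p.b / (p.b + I) ** 2
    return np.array(
        [
            [-p.d - p.theta - p.beta * I, -p.beta * S + p.v - p.theta + dtreat],
            [p.beta * I, p.beta * S - (p.d + p.v) - dtreat],
        ]
    )


def compute_R0(p: ModelParams) -> float:
    """Basic reproduction number R0 = A*b*beta / (d*(c + b*(d+v)))."""
    return p.A * p.b * p.beta / (p.d * (p.c + p.b * (p.d + p.v)))


def thresholds(p: ModelParams) -> tuple[float, float]:
    """Return (A1, Rhat0).

    ``A1 = b*d + d*(d+v)/beta`` separates the forward regime (A <= A1)
    from the backward-bifurcation regime (A > A1).  ``Rhat0`` in (0, 1]
    is the saddle-node value of R0 below which, for A > A1, no endemic
    state exists.
    """
    A1 = p.b * p.d + p.d * (p.d + p.v) / p.beta
    num = 4 * p.A * p.b * p.d * p.beta**2
    sq = (p.d**2 + p.d * p.v + p.b * p.d * p.beta - p.A * p.beta) ** 2
    return A1, num / (num + sq)


def H_index(I: float, p: ModelParams, paper_literal: bool = False) -> float:
    """Trace-based stability index H(I) = theta + d + beta*I - c*I/(b+I)^2.

    At an endemic equilibrium (A/d - I, I) this equals minus the trace of
    the Jacobian, so H > 0 means a stable node/focus and H < 0 unstable.
    ``paper_literal=True`` adds a ``+q`` term as sometimes written for the
    continuously-vaccinated variant of the model; the planar system here
    contains no q, so the default omits it.
    """
    h = p.theta + p.d + p.beta * I - p.c * I / (p.b + I) ** 2
    if paper_literal:
        h += p.q
    return h


@dataclass(frozen=True)
class Equilibrium:
    S: float
    I: float
    multiplicity: int
    H: float
    stability: str  # "stable node" | "stable focus" | "unstable node" | "unstable focus" | "center (linear)"


@dataclass
class EquilibriumReport:
    """Equilibrium structure of the planar system for one parameter set."""

    params: ModelParams
    R0: float
    Rhat0: float
    A1: float
    a1: float
    a2: float
    Delta: float
    dfe: tuple[float, float]
    dfe_stable: bool
    endemics: list[Equilibrium] = field(default_factory=list)
    case: str = "boundary"

    def to_csv(self, path) -> None:
        from .io import write_report_csv

        write_report_csv(self, path)


def _stability_label(S: float, I: float, p: ModelParams, paper_literal: bool = False) -> tuple[float, str]:
    """Classify an endemic point from the Jacobian trace/determinant."""
    H = H_index(I, p, paper_literal=paper_literal)
    J = jacobian(S, I, p)
    tr = float(np.trace(J))
    det = float(np.linalg.det(J))
    disc = tr * tr - 4 * det
    if abs(H) <= BOUNDARY_TOL * max(1.0, p.theta + p.d):
        return H, "center (linear)"
    kind = "node" if disc >= 0 else "focus"
    return H, ("stable " if H > 0 else "unstable ") + kind


def endemic_equilibria(p: ModelParams, paper_literal: bool = False) -> EquilibriumReport:
    """Locate and classify all equilibria of the planar system.

    The endemic I-coordinates are the positive roots of the quadratic
    I^2 + a1*I + a2 = 0 that also satisfy 0 < I < A/d.  A double root
    (discriminant zero within tolerance) is reported once with
    multiplicity 2.  Parameter sets sitting on a case boundary (R0 = 1 or
    zero discriminant within tolerance) get case label ``"boundary"``.
    ``paper_literal`` switches the reported H to the printed variant with
    the extra +q term (comparison only; the sign-based label follows it).
    """
    R0 = compute_R0(p)
    A1, Rhat0 = thresholds(p)
    a1 = p.b + (p.d + p.v) / p.beta - p.A / p.d
    a2 = (p.c + p.b * (p.d + p.v)) / p.beta - p.b * p.A / p.d
    Delta = a1 * a1 - 4 * a2

    endemics: list[Equilibrium] = []
    tol_delta = BOUNDARY_TOL * max(1.0, a1 * a1)
    if abs(Delta) <= tol_delta:
        I = -a1 / 2
        if I > 0 and I < p.A / p.d:
            S = p.A / p.d - I
            H, lab = _stability_label(S, I, p, paper_literal)
            endemics.append(Equilibrium(S, I, 2, H, lab))
    elif Delta > 0:
        sq = math.sqrt(Delta)
        for I in ((-a1 - sq) / 2, (-a1 + sq) / 2):
            if I > BOUNDARY_TOL and I < p.A / p.d:
                S = p.A / p.d - I
                H, lab = _stability_label(S, I, p, paper_literal)
                endemics.append(Equilibrium(S, I, 1, H, lab))

    return EquilibriumReport(
        params=p,
        R0=R0,
        Rhat0=Rhat0,
        A1=A1,
        a1=a1,
        a2=a2,
        Delta=Delta,
        dfe=(p.A / p.d, 0.0),
        dfe_stable=R0 < 1,
        endemics=endemics,
        case=classify_case(p),
    )


def classify_case(p: ModelParams, paper_literal: bool = False) -> str:
    """Classify the ODE phase portrait into cases C1-C4.

    C1: R0 < 1 and A <= A1, or R0 < Rhat0 and A > A1 (disease-free state
        globally attracting);
    C2: R0 > 1 and H(I*) > 0 (unique endemic point, stable);
    C3: R0 > 1 and H(I*) < 0 (unique endemic point, unstable);
    C4: Rhat0 < R0 < 1 and A > A1 (two endemic points, backward regime).

    Parameter sets on the dividing surfaces (within ``BOUNDARY_TOL``)
    return ``"boundary"`` rather than forcing a branch.
    """
    R0 = compute_R0(p)
    A1, Rhat0 = thresholds(p)
    if abs(R0 - 1) <= BOUNDARY_TOL:
        return "boundary"
    if R0 < 1:
        if p.A <= A1:
            return "C1"
        if abs(R0 - Rhat0) <= BOUNDARY_TOL:
            return "boundary"
        if R0 < Rhat0:
            return "C1"
        return "C4"
    # R0 > 1: unique endemic state, larger quadratic root
    a1 = p.b + (p.d + p.v) / p.beta - p.A / p.d
    a2 = (p.c + p.b * (p.d + p.v)) / p.beta - p.b * p.A / p.d
    Delta = a1 * a1 - 4 * a2
    I_star = (-a1 + math.sqrt(max(Delta, 0.0))) / 2
    H = H_index(I_star, p, paper_literal=paper_literal)
    if abs(H) <= BOUNDARY_TOL * max(1.0, p.theta + p.d):
        return "boundary"
    return "C2" if H > 0 else "C3"
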