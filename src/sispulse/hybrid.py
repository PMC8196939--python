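"""Event-driven integration of the pulsed SIS system.

Between pulses the state follows the smooth vector field; whenever the
susceptible count reaches the threshold S_T from below, the pulse map

    planar:  (S, I)    ->  ((1-q) S, I)
    3-comp:  (S, I, V) ->  ((1-q) S, I, V + q S)

is applied and integration restarts from the post-pulse state.  The state
AT a pulse time is the pre-pulse value (left-continuous convention); the
post value is recorded separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model_core import _rhs
from .params import ModelParams

__all__ = [
    "Trajectory",
    "DomainExitError",
    "impulse_map",
    "simulate",
    "simulate3d",
]

#: default solver settings; the Poincare-map derivative stack needs
#: integration errors well below the finite-difference steps it uses
RTOL = 1e-10
ATOL = 1e-12
METHOD = "DOP853"


class DomainExitError(RuntimeError):
    """Trajectory left the invariant set by more than the tolerance."""


def advance_to_threshold(rhs, t0, y0, t_end, p, rtol=RTOL, atol=ATOL, method=METHOD):
    """Integrate ``rhs`` from (t0, y0) until the first upward crossing of
    S = S_T or until t_end.

    Returns ``(ts, ys, t_hit, y_hit)`` with the sampled arc (ys shape
    (n, k), ending at the crossing when one occurred) and the crossing
    time/state or ``(None, None)``.

    A plain terminal event on S - S_T misses grazing passages: near a
    tangency the excursion above the threshold is shorter than an
    integrator step, and the sign at the step endpoints never changes.  A
    second terminal event on dS/dt (every local maximum of S is a
    transversal sign change, so it is always caught) guards against
    this: when integration stops at an S-maximum at or above the
    threshold, the crossing just before it is recovered from the dense
    output by bisection.
    """

    def thresh(t, y):
        return y[0] - p.S_T

    thresh.terminal = True
    thresh.direction = 1.0

    def s_max(t, y):  # non-terminal bookkeeping of local maxima of S
        return rhs(t, y)[0]

    s_max.terminal = False
    s_max.direction = -1.0

    sol = solve_ivp(rhs, (t0, t_end), np.asarray(y0, dtype=float), method=method,
                    rtol=rtol, atol=atol, events=(thresh, s_max), dense_output=True)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"integration failed: {sol.message}")

    t_hit = float(sol.t_events[0][0]) if sol.t_events[0].size else None
    # a grazing passage earlier than the detected crossing (or with no
    # crossing detected at all) shows up as an S-maximum at/above S_T
    for t_top, y_top in zip(sol.t_events[1], sol.y_events[1]):
        if y_top[0] >= p.S_T and (t_hit is None or t_top < t_hit):
            # S < S_T strictly before this excursion (an earlier excursion
            # would have produced an earlier qualifying maximum), so the
            # last sub-threshold sample before the maximum brackets the
            # first upward crossing
            grid = np.linspace(t0, t_top, 512)
            below = np.nonzero(sol.sol(grid)[0] < p.S_T)[0]
            if below.size:
                t_hit = brentq(lambda tt: sol.sol(tt)[0] - p.S_T,
                               grid[below[-1]], t_top, xtol=1e-13)
            else:  # pragma: no cover - started at the threshold
                t_hit = float(t_top)
            break

    if t_hit is None:
        return sol.t, sol.y, None, None
    y_hit = sol.sol(t_hit).copy()
    y_hit[0] = p.S_T
    keep = sol.t < t_hit
    ts = np.append(sol.t[keep], t_hit)
    ys = np.hstack([sol.y[:, keep], y_hit.reshape(-1, 1)])
    return ts, ys, float(t_hit), y_hit


def impulse_map(state, p: ModelParams):
    """Apply the vaccination pulse to a planar or 3-compartment state."""
    if len(state) == 2:
        S, I = state
        return ((1 - p.q) * S, I)
    S, I, V = state
    return ((1 - p.q) * S, I, V + p.q * S)


@dataclass
class Trajectory:
    """Piecewise-smooth hybrid orbit with pulse bookkeeping.

    ``segments`` holds one (t, y) pair per inter-pulse arc, y with shape
    (n_states, n_points).  ``pre_states[k]`` is the state at
    ``impulse_times[k]`` just before the pulse, ``post_states[k]`` just
    after.  ``termination`` is one of ``"horizon"``, ``"max_impulses"``,
    ``"converged"``.
    """

    segments: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    impulse_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    pre_states: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    post_states: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    termination: str = "horizon"

    @property
    def n_impulses(self) -> int:
        return len(self.impulse_times)

    def final_state(self) -> np.ndarray:
        return self.segments[-1][1][:, -1]

    def final_time(self) -> float:
        return self.segments[-1][0][-1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: t, S, I[, V], segment_index, is_impulse.

        Pulse times appear twice: the pre-pulse row closes one segment,
        the post-pulse row opens the next; both carry is_impulse = 1.
        """
        ndim = self.segments[0][1].shape[0]
        cols = ["S", "I", "V"][:ndim]
        rows = []
        for k, (t, y) in enumerate(self.segments):
            df = pd.DataFrame(y.T, columns=cols)
            df.insert(0, "t", t)
            df["segment_index"] = k
            df["is_impulse"] = 0
            if k < self.n_impulses:
                df.iloc[-1, df.columns.get_loc("is_impulse")] = 1
            if k > 0:
                df.iloc[0, df.columns.get_loc("is_impulse")] = 1
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def _check_domain(y: np.ndarray, p: ModelParams, tol: float) -> None:
    S, I = y[0], y[1]
    N = y.sum(axis=0)
    if (S < -tol).any() or (I < -tol).any():
        raise DomainExitError("negative compartment beyond tolerance")
    if y.shape[0] == 2 and (N > p.A / p.d + tol).any():
        raise DomainExitError("S + I exceeded A/d beyond tolerance")


def _simulate(
    rhs,
    y0: np.ndarray,
    p: ModelParams,
    horizon: float,
    max_impulses: int,
    rtol: float,
    atol: float,
    method: str,
    domain_tol: float,
    t0: float = 0.0,
) -> Trajectory:
    """Shared hybrid loop for the planar and 3-compartment systems."""
    ndim = len(y0)
    window = 10.0 / (p.d + p.theta)  # no-progress window for convergence
    traj = Trajectory(pre_states=np.empty((0, ndim)), post_states=np.empty((0, ndim)))
    impulse_times: list[float] = []
    pre: list[np.ndarray] = []
    post: list[np.ndarray] = []

    y = np.asarray(y0, dtype=float)
    if y[0] >= p.S_T:  # start exactly on the threshold: pulse fires at t0
        if y[0] > p.S_T:
            raise ValueError("initial S must not exceed S_T")
        impulse_times.append(t0)
        pre.append(y.copy())
        y = np.asarray(impulse_map(y, p), dtype=float)
        post.append(y.copy())

    t = t0
    seg_t: list[np.ndarray] = []
    seg_y: list[np.ndarray] = []
    prev_max_S = -np.inf
    termination = "horizon"

    def close_segment():
        traj.segments.append((np.concatenate(seg_t), np.concatenate(seg_y, axis=1)))
        seg_t.clear()
        seg_y.clear()

    while t < horizon:
        t_chunk = min(horizon, t + window)
        ts, ys, t_hit, y_hit = advance_to_threshold(
            rhs, t, y, t_chunk, p, rtol=rtol, atol=atol, method=method)
        _check_domain(ys, p, domain_tol)
        seg_t.append(ts)
        seg_y.append(ys)
        if t_hit is not None:  # pulse fired
            t = t_hit
            impulse_times.append(t)
            pre.append(y_hit.copy())
            y = np.asarray(impulse_map(y_hit, p), dtype=float)
            post.append(y.copy())
            # pre-pulse point closes the segment (last sample appended above)
            close_segment()
            seg_t.append(np.array([t]))
            seg_y.append(y.reshape(-1, 1))
            prev_max_S = -np.inf
            if len(impulse_times) >= max_impulses:
                termination = "max_impulses"
                break
        else:
            t = float(ts[-1])
            y = ys[:, -1]
            chunk_max_S = float(ys[0].max())
            if t < horizon and chunk_max_S <= prev_max_S + 1e-10:
                # S made no progress toward S_T over a full window: the
                # orbit is attracted to an interior state with S < S_T
                termination = "converged"
                break
            prev_max_S = chunk_max_S

    if seg_t:
        close_segment()
    traj.impulse_times = np.asarray(impulse_times)
    traj.pre_states = np.asarray(pre).reshape(-1, ndim)
    traj.post_states = np.asarray(post).reshape(-1, ndim)
    traj.termination = termination
    return traj


def simulate(
    p: ModelParams,
    init,
    horizon: float,
    max_impulses: int = 10_000,
    rtol: float = RTOL,
    atol: float = ATOL,
    method: str = METHOD,
    domain_tol: float = 1e-6,
) -> Trajectory:
    """Integrate the planar pulsed system from ``init = (S0, I0)``.

    ``init`` must lie in D with S0 <= S_T; inits above the threshold are
    rejected rather than pulsed immediately.
    """
    S0, I0 = float(init[0]), float(init[1])
    if S0 > p.S_T:
        raise ValueError(f"initial S = {S0} exceeds the threshold S_T = {p.S_T}")
    if S0 < 0 or I0 < 0 or S0 + I0 > p.A / p.d + 1e-9:
        raise ValueError(f"initial state ({S0}, {I0}) outside the invariant set D")

    def rhs(t, y):
        return _rhs(y[0], y[1], p)

    return _simulate(rhs, np.array([S0, I0]), p, horizon, max_impulses, rtol, atol, method, domain_tol)


def simulate3d(
    p: ModelParams,
    init,
    horizon: float,
    max_impulses: int = 10_000,
    rtol: float = RTOL,
    atol: float = ATOL,
    method: str = METHOD,
    domain_tol: float = 1e-6,
) -> Trajectory:
    """Integrate the 3-compartment pulsed system from ``init = (S0, I0, V0)``.

    The total N = S + I + V obeys dN/dt = A - d*N between pulses and is
    conserved across pulses, so N(t) = A/d + (N0 - A/d) e^{-d t} along
    the whole hybrid orbit.
    """
    y0 = np.asarray(init, dtype=float)
    if y0.shape != (3,):
        raise ValueError("init must be (S0, I0, V0)")
    if (y0 < 0).any():
        raise ValueError("initial compartments must be nonnegative")
    if y0[0] > p.S_T:
        raise ValueError(f"initial S = {y0[0]} exceeds the threshold S_T = {p.S_T}")

    def rhs(t, y):
        S, I, V = y
        treat = p.c * I / (p.b + I)
        dS = p.A - p.d * S - p.beta * S * I + p.v * I + p.theta * V + treat
        dI = p.beta * S * I - (p.d + p.v) * I - treat
        dV = -(p.theta + p.d) * V
        return (dS, dI, dV)

    return _simulate(rhs, y0, p, horizon, max_impulses, rtol, atol, method, domain_tol)
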