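"""Structural model: ODE right-hand side, numerical solver, linear oracle.

The drug enters the first of five transit compartments as an instantaneous
bolus at each dose time, cascades with rate k_tr = (NN+1)/MTT into an
absorption compartment, is absorbed with rate ka into the central
compartment (volume V), and is cleared with first-order clearance CL
scaled by the auto-inhibition multiplier

    RCLF + (1 - RCLF) * (1 - Ci / (IC50 + Ci)),

where Ci, the concentration in an empirical inhibition compartment,
relaxes toward the central concentration with rate k_IC.  With inhibition
disabled the whole system is linear and admits a matrix-exponential
closed-form solution, used here as an independent oracle for the
numerical solver.

Parameters may change at occasion boundaries (inter-occasion variability);
``solve_profile`` accepts either a single parameter set or a list of
``(start_time, IndividualParameters)`` segments and carries the state
continuously across doses and segment switches.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import expm

from ._integrate import NSTATE, integrate_breakpoints
from .params import IndividualParameters, PopulationParameters, clearance_multiplier

__all__ = [
    "DoseEvent",
    "ConcentrationProfile",
    "SolverError",
    "ode_rhs",
    "solve_profile",
    "solve_profile_linear",
    "system_matrix",
]

# state layout (see _integrate): A1..A5, Aa, Ac, Ci, Ae, AUCc
IDX_AC = 6
IDX_CI = 7
IDX_AE = 8
IDX_AUC = 9


@dataclass(frozen=True)
class DoseEvent:
    """A bolus of ``amount`` mg into the first transit compartment."""

    time: float
    amount: float

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")


class SolverError(RuntimeError):
    """Raised when the integrator fails to converge; carries diagnostics."""


@dataclass(frozen=True)
class ConcentrationProfile:
    """Solved trajectories on the requested evaluation grid.

    ``conc`` is the central concentration Ac/V (mg/L, total drug),
    ``inhib_conc`` the inhibition-compartment concentration, ``auc`` the
    running integral of ``conc`` since the start of the simulation, and
    ``states`` the full state matrix (one row per time).  Values at dose
    times are pre-dose (trough) values.
    """

    times: np.ndarray
    conc: np.ndarray
    inhib_conc: np.ndarray
    auc: np.ndarray
    states: np.ndarray
    doses: tuple[DoseEvent, ...]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def value_at(self, t: float) -> float:
        """Central concentration at an exact grid time."""
        i = int(np.searchsorted(self.times, t))
        if i >= len(self.times) or self.times[i] != t:
            raise KeyError(f"time {t} not on the evaluation grid")
        return float(self.conc[i])


def ode_rhs(state: np.ndarray, ind: IndividualParameters,
            pop: PopulationParameters, inhibition: bool = True) -> np.ndarray:
    """Time derivative of the model state (pure function, reference path).

    Accepts the 8 dynamic states (A1..A5, Aa, Ac, Ci) or the full 10-state
    vector including the eliminated-amount and AUC bookkeeping integrals.
    """
    state = np.asarray(state, dtype=float)
    if state.shape[0] not in (8, NSTATE):
        raise ValueError("state must have 8 or 10 entries")
    ktr, ka, CL, V = ind.ktr, ind.ka, ind.CL, ind.V
    A = state[:5]
    Aa, Ac, Ci = state[5], state[6], state[7]
    mult = clearance_multiplier(max(Ci, 0.0), pop.RCLF, pop.IC50) if inhibition else 1.0
    elim = (CL / V) * Ac * mult
    d = np.empty_like(state)
    d[0] = -ktr * A[0]
    d[1:5] = ktr * (A[:4] - A[1:])
    d[5] = ktr * A[4] - ka * Aa
    d[6] = ka * Aa - elim
    d[7] = pop.kIC * (Ac / V - Ci)
    if state.shape[0] == NSTATE:
        d[8] = elim
        d[9] = Ac / V
    return d


def _as_segments(
    ind: IndividualParameters | Sequence[tuple[float, IndividualParameters]],
    t0: float,
) -> list[tuple[float, IndividualParameters]]:
    if isinstance(ind, IndividualParameters):
        return [(t0, ind)]
    segs = sorted(ind, key=lambda s: s[0])
    if not segs:
        raise ValueError("at least one parameter segment is required")
    if segs[0][0] > t0:
        raise ValueError("first parameter segment must start at or before t0")
    return [(float(t), p) for t, p in segs]


def _breakpoints(doses: Sequence[DoseEvent], segs, eval_times: np.ndarray):
    t0 = min([eval_times[0]] + [d.time for d in doses] + [segs[0][0]])
    ts = {t0}
    ts.update(d.time for d in doses)
    ts.update(t for t, _ in segs if t > t0)
    ts.update(float(t) for t in eval_times)
    break_ts = np.array(sorted(ts))
    dose_amts = np.zeros_like(break_ts)
    for d in doses:
        dose_amts[np.searchsorted(break_ts, d.time)] += d.amount
    seg_starts = [t for t, _ in segs]
    theta = np.empty((len(break_ts) - 1, 4))
    for i in range(len(break_ts) - 1):
        p = segs[bisect_right(seg_starts, break_ts[i]) - 1][1]
        theta[i] = (p.CL, p.V, p.ka, p.ktr)
    return break_ts, dose_amts, theta


def solve_profile(
    ind: IndividualParameters | Sequence[tuple[float, IndividualParameters]],
    doses: Iterable[DoseEvent],
    eval_times: Sequence[float],
    pop: PopulationParameters,
    *,
    inhibition: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    initial_state: np.ndarray | None = None,
) -> ConcentrationProfile:
    """Simulate a dosing history and return the profile on ``eval_times``.

    Doses are boluses into the first transit compartment; the integration
    restarts at every dose/segment/output time so the returned values at
    dose times are pre-dose.  All compartments start at zero (Ci(0) = 0)
    unless ``initial_state`` is given.
    """
    doses = sorted(doses, key=lambda d: d.time)
    eval_times = np.asarray(sorted(set(float(t) for t in eval_times)))
    if eval_times.size == 0:
        raise ValueError("eval_times must be non-empty")
    segs = _as_segments(ind, min(eval_times[0], doses[0].time if doses else eval_times[0]))
    break_ts, dose_amts, theta = _breakpoints(doses, segs, eval_times)
    if initial_state is None:
        y0 = np.zeros(NSTATE)
    else:
        y0 = np.asarray(initial_state, dtype=float).copy()
        if y0.shape != (NSTATE,):
            raise ValueError(f"initial_state must have {NSTATE} entries")
    Y, status = integrate_breakpoints(
        break_ts, dose_amts, theta, y0,
        pop.kIC, pop.IC50, pop.RCLF, inhibition, rtol, atol,
    )
    if status != 0:
        raise SolverError(
            f"step size underflow (rtol={rtol}, atol={atol}, "
            f"{len(break_ts)} breakpoints on [{break_ts[0]}, {break_ts[-1]}])"
        )
    idx = np.searchsorted(break_ts, eval_times)
    V_at = np.empty(len(eval_times))
    seg_starts = [t for t, _ in segs]
    for j, t in enumerate(eval_times):
        V_at[j] = segs[bisect_right(seg_starts, t) - 1][1].V
    states = Y[idx]
    return ConcentrationProfile(
        times=eval_times,
        conc=states[:, IDX_AC] / V_at,
        inhib_conc=states[:, IDX_CI],
        auc=states[:, IDX_AUC],
        states=states,
        doses=tuple(doses),
    )


def system_matrix(ind: IndividualParameters, pop: PopulationParameters) -> np.ndarray:
    """System matrix of the inhibition-off (linear) model, 10x10."""
    ktr, ka, CL, V = ind.ktr, ind.ka, ind.CL, ind.V
    A = np.zeros((NSTATE, NSTATE))
    A[0, 0] = -ktr
    for i in range(1, 5):
        A[i, i - 1] = ktr
        A[i, i] = -ktr
    A[5, 4] = ktr
    A[5, 5] = -ka
    A[6, 5] = ka
    A[6, 6] = -CL / V
    A[7, 6] = pop.kIC / V
    A[7, 7] = -pop.kIC
    A[8, 6] = CL / V
    A[9, 6] = 1.0 / V
    return A


def solve_profile_linear(
    ind: IndividualParameters | Sequence[tuple[float, IndividualParameters]],
    doses: Iterable[DoseEvent],
    eval_times: Sequence[float],
    pop: PopulationParameters,
    *,
    initial_state: np.ndarray | None = None,
) -> ConcentrationProfile:
    """Matrix-exponential closed-form solution of the inhibition-off model.

    Independent oracle for ``solve_profile(..., inhibition=False)``: the
    state is propagated exactly between events as expm(A*dt) @ y.
    """
    doses = sorted(doses, key=lambda d: d.time)
    eval_times = np.asarray(sorted(set(float(t) for t in eval_times)))
    segs = _as_segments(ind, min(eval_times[0], doses[0].time if doses else eval_times[0]))
    break_ts, dose_amts, theta = _breakpoints(doses, segs, eval_times)
    y = np.zeros(NSTATE) if initial_state is None else np.asarray(initial_state, float).copy()
    seg_starts = [t for t, _ in segs]
    cache: dict[tuple[int, float], np.ndarray] = {}
    Y = np.empty((len(break_ts), NSTATE))
    Y[0] = y
    y = y.copy()
    y[0] += dose_amts[0]
    for i in range(len(break_ts) - 1):
        dt = break_ts[i + 1] - break_ts[i]
        si = bisect_right(seg_starts, break_ts[i]) - 1
        key = (si, round(dt, 12))
        P = cache.get(key)
        if P is None:
            P = expm(system_matrix(segs[si][1], pop) * dt)
            cache[key] = P
        y = P @ y
        Y[i + 1] = y
        y = y.copy()
        y[0] += dose_amts[i + 1]
    idx = np.searchsorted(break_ts, eval_times)
    states = Y[idx]
    V_at = np.array([segs[bisect_right(seg_starts, t) - 1][1].V for t in eval_times])
    return ConcentrationProfile(
        times=eval_times,
        conc=states[:, IDX_AC] / V_at,
        inhib_conc=states[:, IDX_CI],
        auc=states[:, IDX_AUC],
        states=states,
        doses=tuple(doses),
    )
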