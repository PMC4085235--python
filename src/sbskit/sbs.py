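"""The Stochastic Bulirsch-Stoer (SBS) method.

Each macro step integrates the reaction-rate equations with the modified
midpoint method at substep counts n_q = 2q, accumulates the per-reaction
propensity integrals with a composite trapezoid, Richardson-extrapolates them
through a Neville table, and, once the scaled column error err_k drops to 1
or below, fires ``K_j ~ Poisson(Delta-a_j^extr)`` reactions per channel.
Order (table column) and stepsize are chosen to minimise the work per unit
time, exactly as in the deterministic Bulirsch-Stoer method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .extrapolation import (
    NevilleTable,
    StageFailure,
    column_error,
    neville_extend,
    propensity_integral,
    substep_count,
    work_sequence,
)
from .model import ReactionSystem, SolverSettings, StateVector, propensities
from .reference import StepsizeUnderflowError, Trajectory, TAU_FLOOR_FRACTION

_TINY_ERR = 1e-30


@dataclass
class StepRecord:
    """Diagnostics for one accepted SBS step."""

    t_start: float
    tau_used: float
    k_converged: int
    rejections: int
    work: int
    delta_a_extr: np.ndarray
    sampled_counts: np.ndarray


def candidate_stepsize(
    tau: float,
    err_k: float,
    k: int,
    S1: float,
    S2: float,
    max_growth: float = 4.0,
    remaining: float | None = None,
) -> float:
    """Candidate next stepsize for table column k.

    tau_k = tau * S1 * (S2 / err_k)^(1 / (2(k-1)+1)).  A vanishing error
    engages the growth cap tau*S1*max_growth; the result never exceeds the
    remaining simulation time.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if err_k < _TINY_ERR:
        out = tau * S1 * max_growth
    else:
        out = tau * S1 * (S2 / err_k) ** (1.0 / (2 * (k - 1) + 1))
        out = min(out, tau * max_growth)
    if remaining is not None:
        out = min(out, remaining)
    return out


def select_column(candidates: list[tuple[int, float, int]]) -> tuple[int, float]:
    """Pick the (k, tau_k) minimising the work per unit step W = A_k / tau_k.

    Ties break toward smaller k.
    """
    if not candidates:
        raise ValueError("no candidate columns")
    best = None
    for k, tau_k, a_k in sorted(candidates):
        w = a_k / tau_k
        if best is None or w < best[0] - 1e-15 * abs(best[0]):
            best = (w, k, tau_k)
    return best[1], best[2]


def _build_table(
    sys: ReactionSystem,
    x: StateVector,
    tau: float,
    window: list[int],
    settings: SolverSettings,
) -> tuple[NevilleTable, int | None, int]:
    """Build first-column rows up to the window's top; return the table, the
    accepted column (or None) and the drift-evaluation work spent."""
    table = NevilleTable()
    accepted = None
    q_top = max(window)
    work = 0
    for q in range(1, q_top + 1):
        n_q = substep_count(q)
        delta_a = propensity_integral(sys, x, tau, n_q)
        work += n_q + 1
        neville_extend(table, delta_a, n_q)
        if q >= 2:
            err = column_error(table, q, settings.atol, settings.rtol)
            if q in window and err <= 1.0:
                accepted = q
                break
    if accepted is not None and accepted < q_top:
        # one extra row so the order-increase candidate enters the
        # work-per-unit-step selection (the update still uses `accepted`)
        n_q = substep_count(accepted + 1)
        neville_extend(table, propensity_integral(sys, x, tau, n_q), n_q)
        work += n_q + 1
        column_error(table, accepted + 1, settings.atol, settings.rtol)
    return table, accepted, work


def _poisson_update(
    sys: ReactionSystem, x: StateVector, tau: float, lam: np.ndarray,
    rng: np.random.Generator,
) -> tuple[StateVector | None, np.ndarray]:
    k = rng.poisson(np.maximum(lam, 0.0))
    new = x.counts + sys.effective_net_change @ k
    if np.any(new < 0):
        return None, k
    return StateVector(new, x.time + tau), k


def sbs_step(
    sys: ReactionSystem,
    x: StateVector,
    tau: float,
    settings: SolverSettings,
    rng: np.random.Generator,
    k_window: list[int],
    remaining: float,
    tau_floor: float,
) -> tuple[StepRecord, StateVector, float, list[int]]:
    """One adaptive SBS step.

    Builds the Neville table of propensity integrals over the allowed column
    window, accepts at the first column with err <= 1, samples the Poisson
    update, and returns the efficiency-optimal next stepsize and window.
    Rejections (no convergence, failed stages, or a negative population)
    halve tau and retry.
    """
    rejections = 0
    total_work = 0
    while True:
        if tau < tau_floor:
            raise StepsizeUnderflowError(f"SBS stepsize underflow at t={x.time:.6g}")
        tau_try = min(tau, remaining)
        try:
            table, accepted, work = _build_table(sys, x, tau_try, k_window, settings)
        except StageFailure:
            tau *= 0.5
            rejections += 1
            continue
        total_work += work
        if accepted is None:
            tau *= 0.5
            rejections += 1
            continue
        lam = np.maximum(table.diagonal(accepted), 0.0)
        new_state, k_counts = _poisson_update(sys, x, tau_try, lam, rng)
        if new_state is None:
            tau *= 0.5
            rejections += 1
            continue
        break

    # efficiency-optimal next column/stepsize from the columns actually built
    a_seq = work_sequence(settings.k_max)
    candidates = []
    for q, err in table.errs.items():
        tau_q = candidate_stepsize(
            tau_try, err, q, settings.S1, settings.S2, settings.max_growth
        )
        candidates.append((q, tau_q, int(a_seq[q - 1])))
    k_star, tau_star = select_column(candidates)
    next_window = [q for q in (k_star - 1, k_star, k_star + 1) if 2 <= q <= settings.k_max]
    record = StepRecord(
        t_start=x.time,
        tau_used=tau_try,
        k_converged=accepted,
        rejections=rejections,
        work=total_work,
        delta_a_extr=lam,
        sampled_counts=k_counts,
    )
    return record, new_state, tau_star, next_window


def initial_tau(sys: ReactionSystem, x0: StateVector, settings: SolverSettings,
                T: float) -> float:
    """Initial stepsize: explicit settings.tau0, else a multiple of the
    expected SSA waiting time 1/a_0(x_0)."""
    if settings.tau0 is not None:
        return min(settings.tau0, T - x0.time)
    a0 = propensities(sys, x0.counts).sum()
    if a0 <= 0:
        return T - x0.time
    return min(settings.tau0_multiple / a0, T - x0.time)


def sbs_simulate(
    sys: ReactionSystem,
    x0: StateVector,
    T: float,
    settings: SolverSettings,
    rng: np.random.Generator,
    record: bool = False,
) -> tuple[Trajectory, list[StepRecord]]:
    """Full adaptive SBS run to exactly ``T``.

    The first step tests columns upward from q=2 to k_max; subsequent steps
    test only the window {k-1, k, k+1} around the previously optimal column.
    """
    if T <= x0.time:
        raise ValueError("horizon must exceed the initial time")
    state = x0.copy()
    tau = initial_tau(sys, x0, settings, T)
    window = list(range(2, settings.k_max + 1))
    traj = Trajectory(method="sbs")
    traj.append(state.time, state.counts)
    records: list[StepRecord] = []
    floor = TAU_FLOOR_FRACTION * (T - x0.time)
    while state.time < T:
        rec, state, tau, window = sbs_step(
            sys, state, tau, settings, rng, window, T - state.time, floor
        )
        records.append(rec)
        traj.stepsizes.append(rec.tau_used)
        if record:
            traj.append(state.time, state.counts)
    if not record:
        traj.append(state.time, state.counts)
    return traj, records


def sbs_fixed_step_mean(
    sys: ReactionSystem, x: StateVector, tau: float, k: int
) -> np.ndarray:
    """Deterministic Poisson parameter of one fixed-stepsize, fixed-column
    SBS step (k=1: single modified midpoint with n=2, no extrapolation)."""
    table = NevilleTable()
    for q in range(1, k + 1):
        n_q = substep_count(q)
        neville_extend(table, propensity_integral(sys, x, tau, n_q), n_q)
    return np.maximum(table.diagonal(k), 0.0)


def sbs_fixed(
    sys: ReactionSystem,
    x0: StateVector,
    T: float,
    tau: float,
    k: int,
    rng: np.random.Generator,
    record: bool = False,
) -> Trajectory:
    """Restricted SBS with fixed stepsize and fixed table column.

    Used for weak-order studies; a negative population aborts the
    realisation (no resampling), so choose regimes where it cannot occur.
    """
    n_steps = round(T / tau)
    if abs(n_steps * tau - T) > 1e-9 * T:
        raise ValueError("T must be an integer multiple of tau")
    state = x0.copy()
    traj = Trajectory(method=f"sbs-fixed-k{k}")
    traj.append(state.time, state.counts)
    for _ in range(n_steps):
        lam = sbs_fixed_step_mean(sys, state, tau, k)
        new_state, _ = _poisson_update(sys, state, tau, lam, rng)
        if new_state is None:
            raise RuntimeError("negative population in fixed-step SBS realisation")
        state = new_state
        if record:
            traj.append(state.time, state.counts)
    if not record:
        traj.append(state.time, state.counts)
    return traj
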