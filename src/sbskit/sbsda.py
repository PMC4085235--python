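"""Degree-of-advancement variant (SBS-DA) and the unbiased tau-leap (UBTL).

Instead of Romberg-integrating the propensities directly, the SBS-DA solves,
within each step, first-order-closed moment ODEs for the per-channel reaction
counts K_j:

    d mu_j / ds  = sum_j' f_{jj'}(X_n) mu_j'(s) + a_j(X_n),   mu_j(0) = 0
    d V_j  / ds  = 2 f_{jj}(X_n) V_j(s) + d mu_j / ds,        V_j(0) = 0

with the reaction-coupling matrix f frozen at the step-start state.  Two
Neville tables extrapolate (mu, V); convergence is gated on the mu table.
Channels with large extrapolated mean (>= 10) are sampled from a rounded
Gaussian with the corrected variance, the rest from a Poisson — the moment
closure is exact only for linear propensities, and the Gaussian branch
compensates for the variance bias at large stepsizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extrapolation import (
    NevilleTable,
    column_error,
    mmp_states,
    neville_extend,
    substep_count,
    work_sequence,
)
from .model import (
    ReactionSystem,
    SolverSettings,
    StateVector,
    propensities,
    reaction_coupling_matrix,
)
from .reference import (
    StepsizeUnderflowError,
    Trajectory,
    TAU_FLOOR_FRACTION,
    tau_select,
)
from .sbs import StepRecord, candidate_stepsize, initial_tau, select_column

GAUSSIAN_THRESHOLD = 10.0  # mean above which a rounded Gaussian replaces the Poisson


@dataclass
class MomentPair:
    """Per-reaction mean and variance of the reaction counts over one step."""

    mu: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.var = np.asarray(self.var, dtype=float)


def moment_rhs(
    sys: ReactionSystem,
    x_n: StateVector,
    mu: np.ndarray,
    var: np.ndarray,
    _cache: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Right-hand side of the frozen-coefficient moment ODEs at (mu, var)."""
    if _cache is None:
        f = reaction_coupling_matrix(sys, x_n.counts.astype(float))
        a = propensities(sys, x_n.counts)
    else:
        f, a = _cache
    dmu = f @ mu + a
    dvar = 2.0 * np.diag(f) * var + dmu
    return dmu, dvar


def integrate_moments(
    sys: ReactionSystem, x_n: StateVector, tau: float, n_sub: int
) -> MomentPair:
    """Advance the moment ODEs over [0, tau] with the modified midpoint
    method from mu = V = 0; V is clamped at zero on output."""
    m = sys.n_reactions
    if tau == 0:
        return MomentPair(np.zeros(m), np.zeros(m))
    f = reaction_coupling_matrix(sys, x_n.counts.astype(float))
    a = propensities(sys, x_n.counts)
    fdiag = np.diag(f)

    def rhs(y: np.ndarray) -> np.ndarray:
        mu, var = y[:m], y[m:]
        dmu = f @ mu + a
        dvar = 2.0 * fdiag * var + dmu
        return np.concatenate([dmu, dvar])

    stages, _ = mmp_states(rhs, np.zeros(2 * m), tau, n_sub)
    end = stages[-1]
    return MomentPair(end[:m], np.maximum(end[m:], 0.0))


def hybrid_sample(moment: MomentPair, rng: np.random.Generator) -> np.ndarray:
    """Per-channel reaction counts: Poisson(mu) below the threshold mean,
    otherwise round(Normal(mu, V)) clamped at zero."""
    mu = np.maximum(moment.mu, 0.0)
    var = np.maximum(moment.var, 0.0)
    k = np.empty(mu.size, dtype=np.int64)
    small = mu < GAUSSIAN_THRESHOLD
    if small.any():
        k[small] = rng.poisson(mu[small])
    big = ~small
    if big.any():
        draws = rng.normal(mu[big], np.sqrt(var[big]))
        k[big] = np.maximum(np.floor(draws + 0.5), 0.0).astype(np.int64)
    return k


def _build_tables(
    sys: ReactionSystem,
    x: StateVector,
    tau: float,
    window: list[int],
    settings: SolverSettings,
) -> tuple[NevilleTable, NevilleTable, int | None, int]:
    """Dual mu/V Neville tables; convergence gated on the mu table."""
    mu_table, var_table = NevilleTable(), NevilleTable()
    accepted = None
    work = 0
    for q in range(1, max(window) + 1):
        n_q = substep_count(q)
        pair = integrate_moments(sys, x, tau, n_q)
        work += n_q + 1
        neville_extend(mu_table, pair.mu, n_q)
        neville_extend(var_table, pair.var, n_q)
        if q >= 2:
            err = column_error(mu_table, q, settings.atol, settings.rtol)
            if q in window and err <= 1.0:
                accepted = q
                break
    if accepted is not None and accepted < max(window):
        # extra row for the order-increase candidate (update uses `accepted`)
        n_q = substep_count(accepted + 1)
        pair = integrate_moments(sys, x, tau, n_q)
        work += n_q + 1
        neville_extend(mu_table, pair.mu, n_q)
        neville_extend(var_table, pair.var, n_q)
        column_error(mu_table, accepted + 1, settings.atol, settings.rtol)
    return mu_table, var_table, accepted, work


def sbs_da_step(
    sys: ReactionSystem,
    x: StateVector,
    tau: float,
    settings: SolverSettings,
    rng: np.random.Generator,
    k_window: list[int],
    remaining: float,
    tau_floor: float,
) -> tuple[StepRecord, StateVector, float, list[int]]:
    """One adaptive SBS-DA step; control flow mirrors the SBS step with the
    propensity-integral table replaced by the dual moment tables."""
    rejections = 0
    total_work = 0
    while True:
        if tau < tau_floor:
            raise StepsizeUnderflowError(f"SBS-DA stepsize underflow at t={x.time:.6g}")
        tau_try = min(tau, remaining)
        mu_table, var_table, accepted, work = _build_tables(
            sys, x, tau_try, k_window, settings
        )
        total_work += work
        if accepted is None:
            tau *= 0.5
            rejections += 1
            continue
        mu = np.maximum(mu_table.diagonal(accepted), 0.0)
        var = np.maximum(var_table.diagonal(accepted), 0.0)
        k_counts = hybrid_sample(MomentPair(mu, var), rng)
        new = x.counts + sys.effective_net_change @ k_counts
        if np.any(new < 0):
            tau *= 0.5
            rejections += 1
            continue
        new_state = StateVector(new, x.time + tau_try)
        break

    a_seq = work_sequence(settings.k_max)
    candidates = []
    for q, err in mu_table.errs.items():
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
        delta_a_extr=mu,
        sampled_counts=k_counts,
    )
    return record, new_state, tau_star, next_window


def sbs_da_simulate(
    sys: ReactionSystem,
    x0: StateVector,
    T: float,
    settings: SolverSettings,
    rng: np.random.Generator,
    record: bool = False,
) -> tuple[Trajectory, list[StepRecord]]:
    """Full adaptive SBS-DA run to exactly ``T``."""
    if T <= x0.time:
        raise ValueError("horizon must exceed the initial time")
    state = x0.copy()
    tau = initial_tau(sys, x0, settings, T)
    window = list(range(2, settings.k_max + 1))
    traj = Trajectory(method="sbsda")
    traj.append(state.time, state.counts)
    records: list[StepRecord] = []
    floor = TAU_FLOOR_FRACTION * (T - x0.time)
    while state.time < T:
        rec, state, tau, window = sbs_da_step(
            sys, state, tau, settings, rng, window, T - state.time, floor
        )
        records.append(rec)
        traj.stepsizes.append(rec.tau_used)
        if record:
            traj.append(state.time, state.counts)
    if not record:
        traj.append(state.time, state.counts)
    return traj, records


def sbs_da_fixed_step_moments(
    sys: ReactionSystem, x: StateVector, tau: float, k: int
) -> MomentPair:
    """Deterministic (mu, V) of one fixed-stepsize, fixed-column SBS-DA step."""
    mu_table, var_table = NevilleTable(), NevilleTable()
    for q in range(1, k + 1):
        n_q = substep_count(q)
        pair = integrate_moments(sys, x, tau, n_q)
        neville_extend(mu_table, pair.mu, n_q)
        neville_extend(var_table, pair.var, n_q)
    return MomentPair(
        np.maximum(mu_table.diagonal(k), 0.0),
        np.maximum(var_table.diagonal(k), 0.0),
    )


def sbs_da_fixed(
    sys: ReactionSystem,
    x0: StateVector,
    T: float,
    tau: float,
    k: int,
    rng: np.random.Generator,
    record: bool = False,
) -> Trajectory:
    """Restricted SBS-DA with fixed stepsize and fixed table column."""
    n_steps = round(T / tau)
    if abs(n_steps * tau - T) > 1e-9 * T:
        raise ValueError("T must be an integer multiple of tau")
    state = x0.copy()
    traj = Trajectory(method=f"sbsda-fixed-k{k}")
    traj.append(state.time, state.counts)
    for _ in range(n_steps):
        pair = sbs_da_fixed_step_moments(sys, state, tau, k)
        k_counts = hybrid_sample(pair, rng)
        new = state.counts + sys.effective_net_change @ k_counts
        if np.any(new < 0):
            raise RuntimeError("negative population in fixed-step SBS-DA realisation")
        state = StateVector(new, state.time + tau)
        if record:
            traj.append(state.time, state.counts)
    if not record:
        traj.append(state.time, state.counts)
    return traj


def ubtl_simulate(
    sys: ReactionSystem,
    x0: StateVector,
    T: float,
    epsilon: float,
    rng: np.random.Generator,
    record: bool = False,
) -> Trajectory:
    """Unbiased tau-leap comparator.

    Stepsize from the leap-condition bound (as for the Euler tau-leap);
    per-step (mu, V) from the moment ODEs at fixed high resolution (n = 8
    with one Richardson extrapolation against n = 16); hybrid Poisson /
    rounded-Gaussian update.
    """
    if T <= x0.time:
        raise ValueError("horizon must exceed the initial time")
    state = x0.copy()
    traj = Trajectory(method="ubtl")
    traj.append(state.time, state.counts)
    floor = TAU_FLOOR_FRACTION * (T - x0.time)
    while state.time < T:
        tau = tau_select(sys, state, epsilon, remaining=T - state.time)
        while True:
            if tau < floor:
                raise StepsizeUnderflowError(
                    f"UBTL stepsize underflow at t={state.time:.6g}"
                )
            coarse = integrate_moments(sys, state, tau, 8)
            fine = integrate_moments(sys, state, tau, 16)
            mu = fine.mu + (fine.mu - coarse.mu) / 3.0
            var = np.maximum(fine.var + (fine.var - coarse.var) / 3.0, 0.0)
            k_counts = hybrid_sample(MomentPair(np.maximum(mu, 0.0), var), rng)
            new = state.counts + sys.effective_net_change @ k_counts
            if np.all(new >= 0):
                break
            tau *= 0.5
        state = StateVector(new, state.time + tau)
        traj.stepsizes.append(tau)
        if record:
            traj.append(state.time, state.counts)
    if not record:
        traj.append(state.time, state.counts)
    return traj
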