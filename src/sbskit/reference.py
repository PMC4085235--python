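"""Baseline stochastic solvers: exact SSA and the adaptive Euler tau-leap."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ReactionSystem, StateVector, propensities

TAU_FLOOR_FRACTION = 1e-12  # stepsize underflow guard, as a fraction of the horizon


@dataclass
class Trajectory:
    """Record of a single realisation: times, states and per-step metadata."""

    times: list[float] = field(default_factory=list)
    states: list[np.ndarray] = field(default_factory=list)
    method: str = ""
    stepsizes: list[float] = field(default_factory=list)

    def append(self, t: float, x: np.ndarray) -> None:
        self.times.append(float(t))
        self.states.append(np.asarray(x, dtype=np.int64).copy())

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_array(self) -> np.ndarray:
        return np.vstack(self.states)


class StepsizeUnderflowError(RuntimeError):
    """Raised when repeated rejections drive tau below the floor."""


def ssa_simulate(
    sys: ReactionSystem,
    x0: StateVector,
    T: float,
    rng: np.random.Generator,
    record: bool = False,
) -> Trajectory:
    """Exact Gillespie path from ``x0.time`` to ``T``.

    Waiting times are exponential with rate ``a_0(x)``; the firing channel is
    chosen with probability ``a_j / a_0``.  An absorbing state (all
    propensities zero) freezes the trajectory to ``T``.
    """
    if T <= x0.time:
        raise ValueError("horizon must exceed the initial time")
    x = x0.counts.astype(np.int64).copy()
    t = x0.time
    nu = sys.effective_net_change
    traj = Trajectory(method="ssa")
    traj.append(t, x)
    while True:
        a = propensities(sys, x)
        a0 = a.sum()
        if a0 <= 0.0:
            break
        t_next = t + rng.exponential(1.0 / a0)
        if t_next > T:
            break
        j = int(np.searchsorted(np.cumsum(a), rng.random() * a0))
        j = min(j, len(a) - 1)
        x = x + nu[:, j]
        t = t_next
        if record:
            traj.append(t, x)
    traj.append(T, x)
    return traj


def _highest_order_factor(sys: ReactionSystem, x: np.ndarray) -> np.ndarray:
    """Per-species g_i of the Cao-Gillespie-Petzold tau-selection scheme.

    g_i accounts for the steepest propensity any reaction consuming species i
    can have: for the highest-order such reaction of order ``o`` requiring
    ``r`` copies of i, g_i = o (r=1), 2 + 1/(x_i-1) (o=r=2),
    (3/2)(2 + 1/(x_i-1)) (o=3, r=2), 3 + 1/(x_i-1) + 2/(x_i-2) (o=r=3).
    """
    n = sys.n_species
    g = np.ones(n)
    orders = sys.reactant_orders.sum(axis=0)  # total order of each reaction
    for i in range(n):
        gi = 0.0
        for j in range(sys.n_reactions):
            r = sys.reactant_orders[i, j]
            if r == 0:
                continue
            o = orders[j]
            xi = max(float(x[i]), 1.0)
            if r == 1:
                cand = float(o)
            elif o == 2 and r == 2:
                cand = 2.0 + 1.0 / max(xi - 1.0, 1.0)
            elif o == 3 and r == 2:
                cand = 1.5 * (2.0 + 1.0 / max(xi - 1.0, 1.0))
            elif o == 3 and r == 3:
                cand = 3.0 + 1.0 / max(xi - 1.0, 1.0) + 2.0 / max(xi - 2.0, 1.0)
            else:
                cand = float(o)
            gi = max(gi, cand)
        g[i] = max(gi, 1.0)
    return g


def tau_select(
    sys: ReactionSystem, x: StateVector, epsilon: float, remaining: float | None = None
) -> float:
    """Leap-condition stepsize bounding the relative propensity change.

    tau = min over non-fixed reactant species i of
    max(eps*x_i/g_i, 1)/|mu_i| and max(eps*x_i/g_i, 1)^2/sigma_i^2, with
    mu_i = sum_j nu_ij a_j and sigma_i^2 = sum_j nu_ij^2 a_j.  Clamped to the
    remaining simulation time; returns the remaining time if nothing moves.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    a = propensities(sys, x.counts)
    nu = sys.effective_net_change
    mu = nu @ a
    sig2 = (nu**2) @ a
    g = _highest_order_factor(sys, x.counts)
    tau = np.inf
    for i in range(sys.n_species):
        if sys.fixed_species[i]:
            continue
        bound = max(epsilon * float(x.counts[i]) / g[i], 1.0)
        if abs(mu[i]) > 0:
            tau = min(tau, bound / abs(mu[i]))
        if sig2[i] > 0:
            tau = min(tau, bound**2 / sig2[i])
    if remaining is not None:
        tau = min(tau, remaining)
    if not np.isfinite(tau):
        tau = remaining if remaining is not None else np.inf
    return tau


def tau_leap_step(
    sys: ReactionSystem, x: StateVector, tau: float, rng: np.random.Generator
) -> StateVector | None:
    """One Euler tau-leap: K_j ~ Poisson(a_j(x) tau); None signals a failed
    step (negative population) so the caller can retry with tau/2."""
    if tau < 0:
        raise ValueError("negative stepsize")
    if tau == 0:
        return x.copy()
    a = propensities(sys, x.counts)
    k = rng.poisson(a * tau)
    new = x.counts + sys.effective_net_change @ k
    if np.any(new < 0):
        return None
    return StateVector(new, x.time + tau)


def tau_leap_simulate(
    sys: ReactionSystem,
    x0: StateVector,
    T: float,
    epsilon: float,
    rng: np.random.Generator,
    record: bool = False,
) -> Trajectory:
    """Adaptive Euler tau-leap to exactly ``T``, halving tau on failures."""
    if T <= x0.time:
        raise ValueError("horizon must exceed the initial time")
    state = x0.copy()
    traj = Trajectory(method="tl")
    traj.append(state.time, state.counts)
    floor = TAU_FLOOR_FRACTION * (T - x0.time)
    while state.time < T:
        tau = tau_select(sys, state, epsilon, remaining=T - state.time)
        while True:
            if tau < floor:
                raise StepsizeUnderflowError(
                    f"tau-leap stepsize underflow at t={state.time:.6g}"
                )
            nxt = tau_leap_step(sys, state, tau, rng)
            if nxt is not None:
                break
            tau *= 0.5
        state = nxt
        traj.stepsizes.append(tau)
        if record:
            traj.append(state.time, state.counts)
    if not record:
        traj.append(state.time, state.counts)
    return traj
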