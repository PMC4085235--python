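"""Deterministic weak-order experiments for the fixed-step solvers.

Two study systems:

* the Yule process X -> 2X (linear), where the chain mean follows an exact
  one-step recursion because the Poisson increment's expectation equals its
  parameter and the parameter is linear in the state; and
* bimolecular annihilation X + Y -> 0 with X(0) = Y(0) (nonlinear), where
  the full distribution of the fixed-step chain is propagated exactly and
  compared with a truncated-CME reference.

Both measurements carry no Monte-Carlo noise, so regression slopes of
log-error against log-stepsize expose the weak order in the mean directly.
"""

from __future__ import annotations

import numpy as np

from .analysis import (
    chain_distribution,
    cme_mean,
    cme_oracle,
    linear_moment_oracle,
    weak_order_slope,
)
from .fixtures import annihilation, yule
from .model import StateVector
from .sbs import sbs_fixed_step_mean
from .sbsda import sbs_da_fixed_step_moments

YULE_C = 0.2
YULE_X0 = 1000
YULE_T = 12.0


def linear_step_multiplier(method: str, k: int, tau: float, c: float = YULE_C) -> float:
    """Per-step mean growth factor g: E[X_{n+1}] = (1 + g) E[X_n].

    The step's Poisson/Gaussian parameter is linear in the state for the
    Yule process, so evaluating it at X = 1 gives the multiplier exactly.
    """
    fx = yule(c=c, x0=1)
    probe = StateVector([1])
    if method == "sbs":
        return float(sbs_fixed_step_mean(fx.system, probe, tau, k)[0])
    if method == "sbsda":
        return float(sbs_da_fixed_step_moments(fx.system, probe, tau, k).mu[0])
    if method == "tl":
        return c * tau
    raise ValueError(f"unknown method {method!r}")


def linear_mean_order(
    method: str,
    k: int,
    taus: list[float],
    c: float = YULE_C,
    x0: int = YULE_X0,
    T: float = YULE_T,
) -> tuple[float, list[float]]:
    """Weak order in the mean on the Yule process via the exact mean
    recursion; returns (regression slope, per-tau absolute errors)."""
    exact_mean, _ = linear_moment_oracle(c, x0, T)
    errs = []
    for tau in taus:
        g = linear_step_multiplier(method, k, tau, c)
        n = round(T / tau)
        if abs(n * tau - T) > 1e-9 * T:
            raise ValueError("T must be an integer multiple of every tau")
        errs.append(abs(x0 * (1.0 + g) ** n - exact_mean))
    return weak_order_slope(taus, errs), errs


def linear_variance_error(
    method: str, k: int, tau: float,
    c: float = YULE_C, x0: int = YULE_X0, T: float = YULE_T,
) -> float:
    """Absolute error of the chain variance on the Yule process.

    For a Poisson increment with state-linear parameter g X_n:
    Var_{n+1} = (1+g)^2 Var_n + g E[X_n] (exact recursion).
    """
    _, exact_var = linear_moment_oracle(c, x0, T)
    g = linear_step_multiplier(method, k, tau, c)
    n = round(T / tau)
    mean, var = float(x0), 0.0
    for _ in range(n):
        var = (1.0 + g) ** 2 * var + g * mean
        mean *= 1.0 + g
    return abs(var - exact_var)


def nonlinear_mean_order(
    method: str,
    k: int,
    taus: list[float],
    x0: int = 50,
    c: float | None = None,
    T: float = 5.0,
) -> tuple[float, list[float]]:
    """Weak order in the mean on X + Y -> 0 via exact distribution
    propagation of the numerical chain against the truncated CME.

    The rate constant defaults to 0.2 / x0 so the initial per-particle
    reaction rate matches the canonical large-population setup.
    """
    if c is None:
        c = 0.2 / x0
    fx = annihilation(c=c, x0=x0, T=T)
    states, probs = cme_oracle(fx.system, fx.x0, T, truncation=x0)
    ref = cme_mean(states, probs, 0)
    state_of = lambda v: np.array([v, v], dtype=np.int64)  # noqa: E731
    errs = []
    for tau in taus:
        v, p = chain_distribution(
            fx.system, fx.x0, tau, T, method=method, k=k,
            state_of=state_of, v_max=x0,
        )
        errs.append(abs(float(np.dot(v, p)) - ref))
    return weak_order_slope(taus, errs), errs
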