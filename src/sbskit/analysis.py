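"""Ensemble analysis and exact oracles.

Histograms on a fixed global grid, the L1 histogram distance, the efficiency
score eta, weak-order slope estimation, and three exact references used in
the order studies: the closed-form Yule moments, a truncated chemical master
equation (CME) solved with a sparse matrix exponential, and the exact
distribution propagation of fixed-stepsize numerical chains (which measures
weak errors without any Monte-Carlo noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import expm_multiply
from scipy.stats import norm as _norm

from .model import ReactionSystem, StateVector, propensities
from .sbs import sbs_fixed_step_mean
from .sbsda import GAUSSIAN_THRESHOLD, sbs_da_fixed_step_moments

_PMF_TAIL = 1e-13  # per-channel kernel truncation


@dataclass
class Histogram:
    """Binned empirical PDF on the global grid origin + m*width."""

    bin_width: int
    origin: int
    start_bin: int  # global index m of the first bin
    probabilities: np.ndarray
    n_samples: int

    @property
    def bin_edges(self) -> np.ndarray:
        m = self.start_bin + np.arange(self.probabilities.size + 1)
        return self.origin + m * self.bin_width


def build_histogram(
    samples: np.ndarray, bin_width: int, origin: int = 0
) -> Histogram:
    """Histogram with half-open bins [origin + m w, origin + (m+1) w)."""
    samples = np.asarray(samples)
    if samples.size == 0:
        raise ValueError("no samples")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    m = np.floor((samples - origin) / bin_width).astype(np.int64)
    start, stop = int(m.min()), int(m.max())
    counts = np.bincount(m - start, minlength=stop - start + 1)
    return Histogram(
        bin_width=int(bin_width),
        origin=int(origin),
        start_bin=start,
        probabilities=counts / samples.size,
        n_samples=int(samples.size),
    )


def histogram_from_pmf(
    values: np.ndarray, pmf: np.ndarray, bin_width: int, origin: int = 0
) -> Histogram:
    """Bin an exact probability mass function onto the same global grid."""
    values = np.asarray(values)
    pmf = np.asarray(pmf, dtype=float)
    m = np.floor((values - origin) / bin_width).astype(np.int64)
    start, stop = int(m.min()), int(m.max())
    probs = np.zeros(stop - start + 1)
    np.add.at(probs, m - start, pmf)
    return Histogram(int(bin_width), int(origin), start, probs, n_samples=0)


def l1_distance(h1: Histogram, h2: Histogram) -> float:
    """Sum over shared-grid bins of |p1 - p2| (a value in [0, 2]).

    Requires identical bin width and origin; the two supports are aligned on
    the global grid automatically.
    """
    if h1.bin_width != h2.bin_width or h1.origin != h2.origin:
        raise ValueError("histograms must share bin width and origin")
    start = min(h1.start_bin, h2.start_bin)
    stop = max(h1.start_bin + h1.probabilities.size, h2.start_bin + h2.probabilities.size)
    p1 = np.zeros(stop - start)
    p2 = np.zeros(stop - start)
    p1[h1.start_bin - start : h1.start_bin - start + h1.probabilities.size] = h1.probabilities
    p2[h2.start_bin - start : h2.start_bin - start + h2.probabilities.size] = h2.probabilities
    return float(np.abs(p1 - p2).sum())


def efficiency(total_errors, runtimes) -> float:
    """Efficiency eta = (sum of histogram errors)^-1 / (sum of runtimes).

    Comparable only between methods sharing bins and error-parameter sweeps;
    a zero total error returns inf (flagged unbounded).
    """
    total_err = float(np.sum(total_errors))
    total_time = float(np.sum(runtimes))
    if total_time <= 0:
        raise ValueError("runtimes must be positive")
    if total_err == 0:
        return float("inf")
    return (1.0 / total_err) / total_time


def weak_order_slope(stepsizes, errors) -> float:
    """Least-squares slope of log(error) against log(stepsize)."""
    stepsizes = np.asarray(stepsizes, dtype=float)
    errors = np.asarray(errors, dtype=float)
    if stepsizes.size < 2:
        raise ValueError("need at least two points")
    if np.any(errors <= 0):
        raise ValueError("errors must be positive (drop exact-zero points)")
    slope, _ = np.polyfit(np.log(stepsizes), np.log(errors), 1)
    return float(slope)


def linear_moment_oracle(c: float, x0: int, T: float) -> tuple[float, float]:
    """Exact mean and variance of the Yule process X -> 2X at time T:
    mean = x0 e^{cT}, var = x0 e^{cT} (e^{cT} - 1)."""
    g = np.exp(c * T)
    return x0 * g, x0 * g * (g - 1.0)


# ---------------------------------------------------------------------------
# truncated CME oracle


def _enumerate_states(
    sys: ReactionSystem, x0: StateVector, truncation: int
) -> tuple[np.ndarray, dict]:
    """Breadth-first reachable states with every non-fixed count <= truncation."""
    nu = sys.effective_net_change
    start = tuple(int(v) for v in x0.counts)
    states = [start]
    index = {start: 0}
    frontier = [start]
    free = ~sys.fixed_species
    while frontier:
        nxt = []
        for s in frontier:
            arr = np.array(s)
            a = propensities(sys, arr)
            for j in range(sys.n_reactions):
                if a[j] <= 0:
                    continue
                t = arr + nu[:, j]
                if np.any(t < 0) or np.any(t[free] > truncation):
                    continue
                key = tuple(int(v) for v in t)
                if key not in index:
                    index[key] = len(states)
                    states.append(key)
                    nxt.append(key)
        frontier = nxt
    return np.array(states, dtype=np.int64), index


def cme_oracle(
    sys: ReactionSystem, x0: StateVector, T: float, truncation: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exact (truncated) CME solution dP/dt = Q P at time T.

    States are enumerated by reachability with every non-fixed copy number
    capped at ``truncation``; flow out of the truncated set is absorbing, and
    a leaked mass above 1e-8 raises.

    Returns
    -------
    states : (n_states, N) array of copy-number vectors
    probs : probability of each state at time T (sums to 1 within 1e-8)
    """
    states, index = _enumerate_states(sys, x0, truncation)
    n = len(states)
    nu = sys.effective_net_change
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for s_idx in range(n):
        arr = states[s_idx]
        a = propensities(sys, arr)
        for j in range(sys.n_reactions):
            if a[j] <= 0:
                continue
            diag[s_idx] -= a[j]  # outflow counted even if target is truncated
            key = tuple(int(v) for v in (arr + nu[:, j]))
            t_idx = index.get(key)
            if t_idx is not None:
                rows.append(t_idx)
                cols.append(s_idx)
                vals.append(a[j])
    rows += list(range(n))
    cols += list(range(n))
    vals += list(diag)
    q = sparse.csc_matrix((vals, (rows, cols)), shape=(n, n))
    p0 = np.zeros(n)
    p0[index[tuple(int(v) for v in x0.counts)]] = 1.0
    if T == 0:
        return states, p0
    p = expm_multiply(q, p0, start=0.0, stop=T, num=2)[-1]
    p = np.maximum(p, 0.0)
    leak = 1.0 - p.sum()
    if leak > 1e-8:
        raise RuntimeError(f"CME truncation leakage {leak:.3g} exceeds 1e-8")
    return states, p


def cme_mean(states: np.ndarray, probs: np.ndarray, species: int = 0) -> float:
    return float(np.dot(states[:, species], probs))


# ---------------------------------------------------------------------------
# exact distribution propagation of fixed-step numerical chains


def _poisson_pmf(lam: float, kmax: int) -> np.ndarray:
    k = np.arange(kmax + 1)
    if lam <= 0:
        out = np.zeros(kmax + 1)
        out[0] = 1.0
        return out
    logp = k * np.log(lam) - lam - np.cumsum(np.concatenate([[0.0], np.log(np.arange(1, kmax + 1))]))
    return np.exp(logp)


def _channel_pmf(mu: float, var: float | None) -> np.ndarray:
    """Per-channel count pmf: Poisson(mu), or the rounded Gaussian with the
    lower tail clamped into K = 0 when mu >= the hybrid threshold and a
    variance is supplied."""
    if var is None or mu < GAUSSIAN_THRESHOLD:
        lam = max(mu, 0.0)
        kmax = int(lam + 12.0 * np.sqrt(lam + 1.0)) + 2
        pmf = _poisson_pmf(lam, kmax)
    else:
        sd = np.sqrt(max(var, 0.0))
        if sd == 0:
            pmf = np.zeros(int(round(mu)) + 1)
            pmf[int(round(mu))] = 1.0
        else:
            kmax = int(mu + 12.0 * sd) + 2
            k = np.arange(kmax + 1)
            upper = _norm.cdf((k + 0.5 - mu) / sd)
            lower = _norm.cdf((k - 0.5 - mu) / sd)
            pmf = upper - lower
            pmf[0] = upper[0]  # negative draws clamp to zero
    # trim negligible tail, renormalise round-off
    keep = np.nonzero(pmf > _PMF_TAIL)[0]
    stop = keep[-1] + 1 if keep.size else 1
    pmf = pmf[:stop]
    return pmf / pmf.sum()


def chain_distribution(
    sys: ReactionSystem,
    x0: StateVector,
    tau: float,
    T: float,
    method: str = "sbs",
    k: int = 2,
    state_of=None,
    v_max: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact state distribution of a fixed-step numerical chain.

    For an effectively one-dimensional system (all species affine in a single
    free count ``v``), propagates the full distribution of the chain through
    ``T / tau`` steps: at each support point the step's per-channel count law
    (deterministically parameterised Poisson, or rounded Gaussian for the
    degree-of-advancement variant) is convolved over the current
    distribution.  No sampling anywhere, so weak errors measured against the
    CME oracle carry no Monte-Carlo noise.

    Parameters
    ----------
    method : "sbs", "sbsda" or "tl"
    k : table column for the SBS variants (ignored for "tl")
    state_of : callable v -> full copy-number vector (defaults to [v] for
        one-species systems)
    v_max : support cap for the free count (defaults to a generous bound)

    Returns
    -------
    v_values : integer support of the free count
    probs : distribution over the support after the final step
    """
    n_steps = round(T / tau)
    if abs(n_steps * tau - T) > 1e-9 * max(T, 1.0):
        raise ValueError("T must be an integer multiple of tau")
    if state_of is None:
        if sys.n_species != 1:
            raise ValueError("state_of required for multi-species systems")
        state_of = lambda v: np.array([v], dtype=np.int64)  # noqa: E731

    # derive the free axis and per-channel free-count jumps from the state map
    nu = sys.effective_net_change
    anchor = np.asarray(state_of(1), dtype=np.int64)
    base = np.asarray(state_of(2), dtype=np.int64) - anchor  # d(state)/dv
    free_axis = int(np.nonzero(base)[0][0])
    step = int(base[free_axis])
    v0, rem = divmod(int(x0.counts[free_axis]) - int(anchor[free_axis]) + step, step)
    if rem != 0 or not np.array_equal(
        np.asarray(state_of(v0), dtype=np.int64), np.asarray(x0.counts)
    ):
        raise ValueError("x0 not on the state_of support")
    d_free = nu[free_axis] // step

    if v_max is None:
        v_max = v0 + 1
        if np.any(d_free > 0):
            v_max = max(4 * v0 + 100, 100)
    p = np.zeros(v_max + 1)
    p[v0] = 1.0

    # cache per-state kernels (deterministic given v)
    kernel_cache: dict[int, list[np.ndarray]] = {}

    def kernels(v: int) -> list[np.ndarray]:
        if v in kernel_cache:
            return kernel_cache[v]
        x = StateVector(np.maximum(state_of(v), 0), 0.0)
        if method == "sbs":
            lam = sbs_fixed_step_mean(sys, x, tau, k)
            out = [_channel_pmf(float(l), None) for l in lam]
        elif method == "sbsda":
            pair = sbs_da_fixed_step_moments(sys, x, tau, k)
            out = [
                _channel_pmf(float(m), float(vv))
                for m, vv in zip(pair.mu, pair.var)
            ]
        elif method == "tl":
            a = propensities(sys, x.counts)
            out = [_channel_pmf(float(aj * tau), None) for aj in a]
        else:
            raise ValueError(f"unknown method {method!r}")
        kernel_cache[v] = out
        return out

    for _ in range(n_steps):
        new_p = np.zeros_like(p)
        for v in np.nonzero(p > 1e-300)[0]:
            mass = p[v]
            # convolve the channels into a distribution over the v-jump
            jump_dist = {0: 1.0}
            for j, pmf in enumerate(kernels(int(v))):
                dj = int(d_free[j])
                nxt: dict[int, float] = {}
                for dv, w in jump_dist.items():
                    for cnt, q in enumerate(pmf):
                        key = dv + dj * cnt
                        nxt[key] = nxt.get(key, 0.0) + w * q
                jump_dist = nxt
            for dv, w in jump_dist.items():
                tgt = int(v) + dv
                tgt = min(max(tgt, 0), v_max)  # boundary lumping (tail mass)
                new_p[tgt] += mass * w
        p = new_p
    return np.arange(v_max + 1), p
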