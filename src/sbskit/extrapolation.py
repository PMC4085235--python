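"""Deterministic extrapolation engine.

Modified-midpoint (Gragg) stages, composite-trapezoid propensity integrals,
and polynomial Richardson extrapolation organised as a Neville table in the
squared substep, exploiting the even-power error expansion of the modified
midpoint method.  The substep sequence is ``n_q = 2q`` (2, 4, 6, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ReactionSystem, StateVector, drift, propensities_real


class StageFailure(RuntimeError):
    """An intermediate deterministic stage left the admissible region."""


def substep_count(q: int) -> int:
    """Bulirsch sequence used here: n_q = 2q."""
    return 2 * q


def mmp_states(
    drift_fn, x0: np.ndarray, tau: float, n_sub: int
) -> tuple[np.ndarray, np.ndarray]:
    """Modified-midpoint stages over one macro step.

    With h = tau/n_sub: z_0 = x0, z_1 = z_0 + h f(z_0),
    z_{m+1} = z_{m-1} + 2 h f(z_m), and the Gragg-smoothed endpoint
    (z_n + z_{n-1} + h f(z_n)) / 2.  Exactly ``n_sub + 1`` drift evaluations.

    Returns
    -------
    stages : (n_sub + 1, len(x0)) array of z_0 .. z_{n_sub}
    smoothed : the smoothed endpoint (diagnostic; the trapezoid below uses
        the raw stages)
    """
    if n_sub < 2 or n_sub % 2 != 0:
        raise ValueError("n_sub must be even and at least 2")
    if tau <= 0:
        raise ValueError("tau must be positive")
    x0 = np.asarray(x0, dtype=float)
    h = tau / n_sub
    stages = np.empty((n_sub + 1, x0.size))
    stages[0] = x0
    stages[1] = x0 + h * drift_fn(x0)
    for m in range(1, n_sub):
        stages[m + 1] = stages[m - 1] + 2.0 * h * drift_fn(stages[m])
    smoothed = 0.5 * (stages[n_sub] + stages[n_sub - 1] + h * drift_fn(stages[n_sub]))
    return stages, smoothed


def propensity_integral(
    sys: ReactionSystem, x0: StateVector, tau: float, n_sub: int
) -> np.ndarray:
    """Per-reaction expected integral of the propensities over one step.

    The reaction-rate equations are advanced with the modified midpoint
    method; propensities evaluated at the raw stages feed a composite
    trapezoid: Delta-a_j = h (a_j(z_0)/2 + sum a_j(z_m) + a_j(z_n)/2).
    """
    if tau == 0:
        return np.zeros(sys.n_reactions)
    stages, _ = mmp_states(lambda y: drift(sys, y), x0.counts.astype(float), tau, n_sub)
    if np.any(stages[:, ~sys.fixed_species] < -1e-9 * (1.0 + np.abs(stages).max())):
        raise StageFailure("deterministic stage went negative")
    h = tau / n_sub
    a = np.array([propensities_real(sys, z) for z in stages])
    weights = np.ones(n_sub + 1)
    weights[0] = weights[-1] = 0.5
    return h * (weights @ a)


@dataclass
class NevilleTable:
    """Triangular table of h^2-polynomial extrapolants of a vector quantity.

    ``rows[q-1]`` holds, after ``q`` first-column entries have been added,
    the extrapolants built from trailing windows ending at row ``q``:
    entry ``r`` of the list is the width-(r+1) extrapolant Y^{tau_{q-r}..tau_q}.
    The diagonal (last element of the last row) is the most accurate value;
    the subdiagonal drives the scaled column error err_q.
    """

    substep_counts: list[int] = field(default_factory=list)
    rows: list[list[np.ndarray]] = field(default_factory=list)
    errs: dict[int, float] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return len(self.rows)

    def diagonal(self, q: int | None = None) -> np.ndarray:
        """Most-extrapolated value using the first q rows (default: all)."""
        q = self.depth if q is None else q
        return self.rows[q - 1][-1]

    def subdiagonal(self, q: int | None = None) -> np.ndarray:
        """Extrapolant from rows 2..q (one fewer extrapolation)."""
        q = self.depth if q is None else q
        if q < 2:
            raise ValueError("subdiagonal needs at least two rows")
        return self.rows[q - 1][-2]


def neville_extend(
    table: NevilleTable, value: np.ndarray, substeps: int
) -> NevilleTable:
    """Append a first-column entry and complete its diagonal (in place).

    The recursion runs in the variable h^2 (even error expansion):
    Y_{q-r,q} = Y_{q-r+1,q} + (Y_{q-r+1,q} - Y_{q-r,q-1}) / ((n_q/n_{q-r})^2 - 1).
    """
    value = np.atleast_1d(np.asarray(value, dtype=float))
    if table.substep_counts and substeps <= table.substep_counts[-1]:
        raise ValueError("substep counts must be strictly increasing")
    table.substep_counts.append(substeps)
    q = len(table.substep_counts)
    row: list[np.ndarray] = [value]
    for r in range(1, q):
        n_q = table.substep_counts[-1]
        n_qr = table.substep_counts[q - 1 - r]
        ratio2 = (n_q / n_qr) ** 2
        upper = row[r - 1]  # Y_{q-r+1, q}
        left = table.rows[q - 2][r - 1]  # Y_{q-r, q-1}
        row.append(upper + (upper - left) / (ratio2 - 1.0))
    table.rows.append(row)
    return table


def column_error(
    table: NevilleTable, q: int, atol: float, rtol: float
) -> float:
    """Scaled internal-consistency error of Romberg column q (q >= 2).

    err_q = ||Y_diag - Y_subdiag||_2 / (atol + rtol * ||Y_diag||_2), the
    L2-norm difference between the best value in column q and the best in
    column q-1, relative to a mixed tolerance.  Acceptance requires
    err_q <= 1.
    """
    if q < 2:
        raise ValueError("column error defined for q >= 2")
    top = table.diagonal(q)
    second = table.subdiagonal(q)
    diff = float(np.linalg.norm(top - second))
    denom = atol + rtol * float(np.linalg.norm(top))
    err = 0.0 if diff == 0.0 else diff / denom
    table.errs[q] = err
    return err


def work_sequence(k: int) -> np.ndarray:
    """Cumulative drift evaluations A_1..A_k: A_1 = 3, A_{q+1} = A_q + n_{q+1}."""
    if k < 1:
        raise ValueError("k must be positive")
    a = np.empty(k, dtype=np.int64)
    a[0] = 3
    for q in range(1, k):
        a[q] = a[q - 1] + substep_count(q + 1)
    return a
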