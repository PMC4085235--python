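"""Mass-action reaction networks: propensities, drift and reaction coupling.

A chemical system of ``N`` species and ``M`` reactions is described by the
reactant multiplicities (left-hand-side stoichiometry), the net stoichiometric
change vectors ``nu_j`` and state-space rate constants ``c_j``.  Propensities
follow Gillespie's combinatorial convention: a reaction consuming ``r`` copies
of a species with ``x`` molecules contributes ``binomial(x, r)`` distinct
reactant combinations, so e.g. a homodimerisation has ``a = c * x*(x-1)/2``.

Species can be flagged *fixed* (chemostatted): they enter propensities with
their constant copy number but are never changed by a reaction firing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ReactionSystem:
    """A mass-action reaction network.

    Parameters
    ----------
    species_names
        Labels for the ``N`` species.
    reactant_orders
        ``(N, M)`` non-negative integer array; entry ``[i, j]`` is the
        multiplicity of species ``i`` on the reactant side of reaction ``j``.
    net_change
        ``(N, M)`` integer array whose columns are the stoichiometric change
        vectors ``nu_j``.
    rate_constants
        ``M`` positive state-space rate constants ``c_j``.
    fixed_species
        ``N`` booleans; fixed species never change copy number.
    """

    species_names: list[str]
    reactant_orders: np.ndarray
    net_change: np.ndarray
    rate_constants: np.ndarray
    fixed_species: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.reactant_orders = np.asarray(self.reactant_orders, dtype=np.int64)
        self.net_change = np.asarray(self.net_change, dtype=np.int64)
        self.rate_constants = np.asarray(self.rate_constants, dtype=float)
        n, m = self.reactant_orders.shape
        if self.fixed_species is None:
            self.fixed_species = np.zeros(n, dtype=bool)
        self.fixed_species = np.asarray(self.fixed_species, dtype=bool)
        if n < 1 or m < 1:
            raise ValueError("need at least one species and one reaction")
        if len(self.species_names) != n:
            raise ValueError("species_names length mismatch")
        if self.net_change.shape != (n, m):
            raise ValueError("net_change shape mismatch")
        if self.rate_constants.shape != (m,):
            raise ValueError("rate_constants shape mismatch")
        if np.any(self.rate_constants <= 0):
            raise ValueError("rate constants must be positive")
        if np.any(self.reactant_orders < 0):
            raise ValueError("reactant orders must be non-negative")

    @property
    def n_species(self) -> int:
        return self.reactant_orders.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.reactant_orders.shape[1]

    @property
    def effective_net_change(self) -> np.ndarray:
        """Net change with fixed-species rows zeroed (used in state updates)."""
        nu = self.net_change.copy()
        nu[self.fixed_species, :] = 0
        return nu

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None


@dataclass
class StateVector:
    """Integer copy numbers at a time point."""

    counts: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("negative copy number")

    def copy(self) -> "StateVector":
        return StateVector(self.counts.copy(), self.time)


@dataclass
class SolverSettings:
    """Control parameters shared by the adaptive solvers.

    ``S1``/``S2`` are the Bulirsch-Stoer safety factors (both in (0,1));
    ``atol``/``rtol`` scale the internal-consistency error of the Romberg
    table; ``k_max`` caps the table depth; ``epsilon`` is the tau-leap
    error-control fraction; ``tau0`` fixes the initial stepsize explicitly,
    or, if None, it is set to ``tau0_multiple / a_0(x_0)``.
    """

    S1: float = 0.25
    S2: float = 0.25
    atol: float = 1e-6
    rtol: float = 1e-6
    k_max: int = 8
    tau0: float | None = None
    tau0_multiple: float = 10.0
    epsilon: float = 0.03
    seed: int = 0
    max_growth: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.S1 < 1 and 0 < self.S2 < 1):
            raise ValueError("safety factors must lie in (0, 1)")
        if self.atol + self.rtol <= 0:
            raise ValueError("atol + rtol must be positive")
        if self.k_max < 2:
            raise ValueError("k_max must be at least 2")


def build_system(
    species: list[str],
    reactions: list[dict],
    fixed: list[str] | None = None,
) -> ReactionSystem:
    """Assemble a validated :class:`ReactionSystem` from a structured description.

    Each reaction dict has keys ``reactants`` and ``products`` (mappings
    species name -> multiplicity), ``c`` (forward rate constant) and
    optionally ``c_rev`` — a reversible reaction expands into two
    irreversible ones, forward first.
    """
    if not reactions:
        raise ValueError("empty reaction list")
    if not species:
        raise ValueError("no species declared")
    index = {s: i for i, s in enumerate(species)}
    fixed = fixed or []
    for s in fixed:
        if s not in index:
            raise ValueError(f"unknown fixed species {s!r}")

    cols_react: list[np.ndarray] = []
    cols_nu: list[np.ndarray] = []
    cs: list[float] = []
    n = len(species)

    def add(reactants: dict, products: dict, c: float) -> None:
        if c <= 0:
            raise ValueError("non-positive rate constant")
        lhs = np.zeros(n, dtype=np.int64)
        rhs = np.zeros(n, dtype=np.int64)
        for side, arr in ((reactants, lhs), (products, rhs)):
            for name, mult in side.items():
                if name not in index:
                    raise ValueError(f"unknown species {name!r} in reaction")
                arr[index[name]] += int(mult)
        cols_react.append(lhs)
        cols_nu.append(rhs - lhs)
        cs.append(float(c))

    for rx in reactions:
        add(rx["reactants"], rx["products"], rx["c"])
        if rx.get("c_rev") is not None:
            add(rx["products"], rx["reactants"], rx["c_rev"])

    fixed_mask = np.zeros(n, dtype=bool)
    for s in fixed:
        fixed_mask[index[s]] = True
    return ReactionSystem(
        species_names=list(species),
        reactant_orders=np.column_stack(cols_react),
        net_change=np.column_stack(cols_nu),
        rate_constants=np.array(cs),
        fixed_species=fixed_mask,
    )


def propensities(sys: ReactionSystem, x: np.ndarray) -> np.ndarray:
    """Mass-action propensities ``a_j(x)`` for integer state ``x``.

    Uses falling-factorial combinatorics: ``r`` reactant copies of a species
    with ``x`` molecules contribute ``x (x-1) ... (x-r+1) / r!`` combinations.
    Zero whenever a reactant count is below its multiplicity.
    """
    x = np.asarray(x)
    if np.any(x < 0):
        raise ValueError("negative copy number")
    return _mass_action(sys, x.astype(float), falling=True)


def _mass_action(sys: ReactionSystem, x: np.ndarray, falling: bool) -> np.ndarray:
    idx_i, idx_j, idx_r = _reactant_index(sys)
    a = sys.rate_constants.copy()
    if idx_i.size:
        xi = x[idx_i]
        if falling:
            term = np.ones_like(xi, dtype=float)
            for d in range(int(idx_r.max())):
                sel = idx_r > d
                term[sel] *= xi[sel] - d
            term /= _FACTORIALS[idx_r]
            np.maximum(term, 0.0, out=term)
        else:
            term = xi.astype(float) ** idx_r / _FACTORIALS[idx_r]
        seg_starts, seg_j = _segment_index(sys)
        a[seg_j] *= np.multiply.reduceat(term, seg_starts)
    return np.maximum(a, 0.0)


_FACTORIALS = np.array([1.0, 1.0, 2.0, 6.0, 24.0, 120.0, 720.0])


def _reactant_index(sys: ReactionSystem) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cached (species, reaction, multiplicity) triples of nonzero reactant
    orders, grouped by reaction, for vectorised propensity evaluation."""
    cached = getattr(sys, "_reactant_idx", None)
    if cached is None:
        i, j = np.nonzero(sys.reactant_orders.T)  # sorted by reaction
        i, j = j, i
        cached = (i, j, sys.reactant_orders[i, j])
        object.__setattr__(sys, "_reactant_idx", cached)
    return cached


def _segment_index(sys: ReactionSystem) -> tuple[np.ndarray, np.ndarray]:
    """Per-reaction segment starts into the reactant-index arrays."""
    cached = getattr(sys, "_segment_idx", None)
    if cached is None:
        _, idx_j, _ = _reactant_index(sys)
        starts = np.nonzero(np.diff(idx_j, prepend=-1))[0]
        cached = (starts, idx_j[starts])
        object.__setattr__(sys, "_segment_idx", cached)
    return cached


def _factorial(r: int) -> float:
    out = 1.0
    for d in range(2, r + 1):
        out *= d
    return out


def propensities_real(sys: ReactionSystem, x: np.ndarray) -> np.ndarray:
    """Real-valued mass-action extension used inside deterministic substeps.

    Same falling-factorial form evaluated at real ``x`` (clamped at zero so a
    slightly negative intermediate stage does not produce a negative rate).
    """
    x = np.asarray(x, dtype=float)
    return _mass_action(sys, x, falling=True)


def drift(sys: ReactionSystem, x: np.ndarray) -> np.ndarray:
    """Reaction-rate-equation right-hand side ``sum_j nu_j a_j(x)``.

    Fixed-species components are zero: a chemostatted population has no
    deterministic motion even though it feeds the propensities.
    """
    a = propensities_real(sys, x)
    return sys.effective_net_change @ a


def reaction_coupling_matrix(sys: ReactionSystem, x: np.ndarray) -> np.ndarray:
    """The M-by-M matrix ``f[j, j'] = sum_i d a_j / d x_i * nu_{i j'}``.

    Partial derivatives are of the real-valued mass-action extension;
    fixed-species rows of ``nu`` are zero, so chemostatted species do not
    couple reactions.
    """
    x = np.asarray(x, dtype=float)
    m = sys.n_reactions
    nu = sys.effective_net_change.astype(float)
    jac = np.zeros((m, sys.n_species))  # d a_j / d x_i
    for j in range(m):
        c = sys.rate_constants[j]
        col = sys.reactant_orders[:, j]
        for i in np.nonzero(col)[0]:
            term = c
            for ii in np.nonzero(col)[0]:
                r = col[ii]
                if ii == i:
                    # derivative of the falling factorial in x_i
                    term *= _falling_deriv(x[ii], r) / _factorial(r)
                else:
                    term *= _falling(x[ii], r) / _factorial(r)
            jac[j, i] = term
    return jac @ nu


def _falling(x: float, r: int) -> float:
    out = 1.0
    for d in range(r):
        out *= x - d
    return out


def _falling_deriv(x: float, r: int) -> float:
    # d/dx of x(x-1)...(x-r+1): sum over dropped factors
    total = 0.0
    for skip in range(r):
        term = 1.0
        for d in range(r):
            if d != skip:
                term *= x - d
        total += term
    return total
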