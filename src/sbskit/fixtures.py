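"""Built-in benchmark systems.

Four standard test networks (chain decay, Michaelis-Menten, Schlögl,
mutually inhibiting enzymes) plus the two small systems used for weak-order
studies (the Yule process X -> 2X and the bimolecular annihilation
X + Y -> 0), each with its canonical parameters, initial state, horizon and
histogram bin widths, and the parameter sweeps used in the efficiency
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ReactionSystem, SolverSettings, StateVector, build_system


@dataclass
class Fixture:
    name: str
    system: ReactionSystem
    x0: StateVector
    T: float
    bin_widths: list[int] = field(default_factory=list)
    # canonical solver parameters for the efficiency studies
    sbs: dict = field(default_factory=dict)
    sbsda: dict = field(default_factory=dict)
    sweeps: dict = field(default_factory=dict)  # method -> list of rtol/epsilon values

    def sbs_settings(self, rtol: float = 1e-5, **overrides) -> SolverSettings:
        """Canonical SBS settings for this system (rtol overridable)."""
        kw = dict(self.sbs)
        kw.update(rtol=rtol, **overrides)
        return SolverSettings(**kw)

    def sbsda_settings(self, rtol: float = 1e-5, **overrides) -> SolverSettings:
        """Canonical SBS-DA settings for this system (rtol overridable)."""
        kw = dict(self.sbsda)
        kw.update(rtol=rtol, **overrides)
        return SolverSettings(**kw)


def chain_decay() -> Fixture:
    """X1 -> X2 -> X3 with unit rates; linear propensities."""
    sys = build_system(
        ["X1", "X2", "X3"],
        [
            {"reactants": {"X1": 1}, "products": {"X2": 1}, "c": 1.0},
            {"reactants": {"X2": 1}, "products": {"X3": 1}, "c": 1.0},
        ],
    )
    return Fixture(
        name="chain_decay",
        system=sys,
        x0=StateVector([10000, 1, 0]),
        T=5.0,
        bin_widths=[2, 5, 5],
        sbs={"S1": 0.2, "S2": 0.4, "atol": 1e-6},
        sbsda={"S1": 0.15, "S2": 0.2, "atol": 1e-6},
        sweeps={
            "sbs": [1e-5, 5e-6, 1e-6, 5e-7, 2.5e-7, 1e-7],
            "sbsda": [1e-5, 5e-6, 1e-6, 5e-7, 1e-7, 1e-8],
            "tl": [0.125, 0.1, 0.075, 0.05, 0.04, 0.03],
            "ubtl": [4, 2, 1, 0.8, 0.6, 0.5],
        },
    )


def michaelis_menten() -> Fixture:
    """Enzyme X2 converts substrate X1 into product X4 via complex X3."""
    sys = build_system(
        ["X1", "X2", "X3", "X4"],
        [
            {"reactants": {"X1": 1, "X2": 1}, "products": {"X3": 1}, "c": 1e-4},
            {"reactants": {"X3": 1}, "products": {"X1": 1, "X2": 1}, "c": 0.5},
            {"reactants": {"X3": 1}, "products": {"X2": 1, "X4": 1}, "c": 0.5},
        ],
    )
    return Fixture(
        name="michaelis_menten",
        system=sys,
        x0=StateVector([1000, 200, 2000, 0]),
        T=10.0,
        bin_widths=[5, 5, 5, 5],
        sbs={"S1": 0.35, "S2": 0.35, "atol": 1e-6},
        sbsda={"S1": 0.33, "S2": 0.33, "atol": 1e-6},
        sweeps={
            "sbs": [1e-2, 1e-3, 1e-4, 1e-5, 1e-6, 1e-7],
            "sbsda": [1e-3, 1e-4, 1e-5, 1e-6, 1e-7, 1e-8],
            "tl": [0.2, 0.15, 0.1, 0.07, 0.05, 0.04],
            "ubtl": [7, 5, 3, 2, 1.5, 1],
        },
    )


def schlogl() -> Fixture:
    """The bimodal Schlögl system; A and B are chemostatted."""
    sys = build_system(
        ["X", "A", "B"],
        [
            {"reactants": {"A": 1, "X": 2}, "products": {"X": 3}, "c": 3e-7},
            {"reactants": {"X": 3}, "products": {"A": 1, "X": 2}, "c": 1e-4},
            {"reactants": {"B": 1}, "products": {"X": 1}, "c": 1e-3},
            {"reactants": {"X": 1}, "products": {"B": 1}, "c": 3.5},
        ],
        fixed=["A", "B"],
    )
    return Fixture(
        name="schlogl",
        system=sys,
        x0=StateVector([250, 100000, 200000]),
        T=10.0,
        bin_widths=[10],
        sbs={"S1": 0.05, "S2": 0.05, "atol": 1e-6},
        sbsda={"S1": 0.125, "S2": 0.125, "atol": 1e-6},
        sweeps={
            "sbs": [1e-5, 8e-6, 4e-6, 1e-6, 5e-7, 1e-7],
            "sbsda": [2e-4, 1.5e-4, 1e-4, 9e-5, 8e-5, 6e-5],
            "tl": [0.046, 0.044, 0.042, 0.04, 0.0375, 0.035],
            "ubtl": [0.3, 0.28, 0.26, 0.24, 0.22, 0.2],
        },
    )


def enzymes() -> Fixture:
    """Two enzymes whose products mutually inhibit the other enzyme.

    Species order [A, B, E_A, E_B, E_AB, E_AB2, E_BA, E_BA2]; 12 reactions
    (reversible binding steps expanded forward-then-reverse).
    """
    sp = ["A", "B", "EA", "EB", "EAB", "EAB2", "EBA", "EBA2"]
    sys = build_system(
        sp,
        [
            {"reactants": {"EA": 1}, "products": {"EA": 1, "A": 1}, "c": 15.0},
            {"reactants": {"EB": 1}, "products": {"EB": 1, "B": 1}, "c": 15.0},
            {"reactants": {"EA": 1, "B": 1}, "products": {"EAB": 1}, "c": 5e-4,
             "c_rev": 2.0},
            {"reactants": {"EAB": 1, "B": 1}, "products": {"EAB2": 1}, "c": 1e-3,
             "c_rev": 6.0},
            {"reactants": {"A": 1}, "products": {}, "c": 5.0},
            {"reactants": {"EB": 1, "A": 1}, "products": {"EBA": 1}, "c": 5e-4,
             "c_rev": 2.0},
            {"reactants": {"EBA": 1, "A": 1}, "products": {"EBA2": 1}, "c": 1e-3,
             "c_rev": 6.0},
            {"reactants": {"B": 1}, "products": {}, "c": 5.0},
        ],
    )
    return Fixture(
        name="enzymes",
        system=sys,
        x0=StateVector([20000, 15000, 9500, 9500, 2000, 500, 2000, 500]),
        T=2.0,
        bin_widths=[100, 100, 50, 50, 50, 50, 50, 50],
        sbs={"S1": 0.4, "S2": 0.4, "atol": 1e-6},
        sbsda={"S1": 0.55, "S2": 0.7, "atol": 1e-6},
        sweeps={
            "sbs": [1e-5, 1e-6, 1e-7, 1e-8, 1e-9, 1e-10],
            "sbsda": [1e-5, 1e-6, 1e-7, 1e-8, 1e-9, 1e-10],
            "tl": [0.15, 0.1, 0.07, 0.05, 0.03, 0.02],
            "ubtl": [5, 3, 1.5, 0.8, 0.4, 0.3],
        },
    )


def yule(c: float = 0.2, x0: int = 1000, T: float = 12.0) -> Fixture:
    """Linear pure-birth process X -> 2X (order-study system)."""
    sys = build_system(
        ["X"], [{"reactants": {"X": 1}, "products": {"X": 2}, "c": c}]
    )
    return Fixture(name="yule", system=sys, x0=StateVector([x0]), T=T,
                   bin_widths=[1])


def annihilation(c: float = 1e-5, x0: int = 10000, T: float = 12.0) -> Fixture:
    """Bimolecular annihilation X + Y -> 0 with X(0) = Y(0) (order-study
    system; X - Y is conserved)."""
    sys = build_system(
        ["X", "Y"], [{"reactants": {"X": 1, "Y": 1}, "products": {}, "c": c}]
    )
    return Fixture(name="annihilation", system=sys,
                   x0=StateVector([x0, x0]), T=T, bin_widths=[1, 1])


FIXTURES = {
    "chain_decay": chain_decay,
    "michaelis_menten": michaelis_menten,
    "schlogl": schlogl,
    "enzymes": enzymes,
    "yule": yule,
    "annihilation": annihilation,
}


def get_fixture(name: str) -> Fixture:
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(sorted(FIXTURES))}"
        ) from None
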