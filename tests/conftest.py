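import numpy as np
import pytest

from sbskit.fixtures import get_fixture
from sbskit.model import build_system, StateVector


@pytest.fixture
def chain_decay():
    return get_fixture("chain_decay")


@pytest.fixture
def yule_system():
    return get_fixture("yule")


@pytest.fixture
def birth_death():
    """0 -> X at rate 5, X -> 0 at unit rate: stationary law Poisson(5)."""
    sys = build_system(
        ["X"],
        [
            {"reactants": {}, "products": {"X": 1}, "c": 5.0},
            {"reactants": {"X": 1}, "products": {}, "c": 1.0},
        ],
    )
    return sys, StateVector([0])


def conservation_vectors(sys):
    """Integer left-null vectors of the effective stoichiometry (rational
    basis via sympy-free scipy nullspace, rounded)."""
    nu = sys.effective_net_change.astype(float)
    u, s, vt = np.linalg.svd(nu.T)
    null_mask = np.concatenate([s, np.zeros(nu.shape[0] - len(s))]) < 1e-10
    basis = vt[np.sum(s > 1e-10):]
    return basis
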