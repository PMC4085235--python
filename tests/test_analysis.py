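import numpy as np
import pytest
from scipy import stats

from sbskit.analysis import (
    build_histogram,
    chain_distribution,
    cme_mean,
    cme_oracle,
    efficiency,
    histogram_from_pmf,
    l1_distance,
    linear_moment_oracle,
    weak_order_slope,
)
from sbskit.fixtures import annihilation, get_fixture
from sbskit.model import StateVector, build_system


class TestHistogram:
    def test_simple_binning(self):
        h = build_histogram(np.array([0, 1, 2, 2, 3, 9]), bin_width=2)
        assert h.start_bin == 0
        np.testing.assert_allclose(h.probabilities, [2 / 6, 3 / 6, 0, 0, 1 / 6])
        np.testing.assert_array_equal(h.bin_edges, [0, 2, 4, 6, 8, 10])

    def test_global_grid_alignment(self):
        # shifted samples land on the same global grid (origin + m w)
        h1 = build_histogram(np.array([0, 1]), 2)
        h2 = build_histogram(np.array([6, 7]), 2)
        assert h1.bin_width == h2.bin_width and h1.origin == h2.origin
        assert h2.start_bin == 3

    def test_pmf_binning_matches_sampling_limit(self):
        vals = np.arange(6)
        pmf = np.array([0.1, 0.2, 0.3, 0.2, 0.1, 0.1])
        h = histogram_from_pmf(vals, pmf, bin_width=2)
        np.testing.assert_allclose(h.probabilities, [0.3, 0.5, 0.2])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_histogram(np.array([]), 2)


class TestL1Distance:
    def test_identical_is_zero(self):
        h = build_histogram(np.array([1, 2, 3]), 2)
        assert l1_distance(h, h) == 0.0

    def test_disjoint_supports_is_two(self):
        h1 = build_histogram(np.array([0, 1]), 2)
        h2 = build_histogram(np.array([100, 101]), 2)
        assert l1_distance(h1, h2) == pytest.approx(2.0)

    def test_symmetry_and_triangle(self):
        rng = np.random.default_rng(0)
        hs = [build_histogram(rng.poisson(20, 200), 2) for _ in range(3)]
        d01 = l1_distance(hs[0], hs[1])
        assert d01 == pytest.approx(l1_distance(hs[1], hs[0]))
        assert d01 <= l1_distance(hs[0], hs[2]) + l1_distance(hs[2], hs[1]) + 1e-12

    def test_mismatched_grids_rejected(self):
        h1 = build_histogram(np.array([1]), 2)
        h2 = build_histogram(np.array([1]), 3)
        with pytest.raises(ValueError):
            l1_distance(h1, h2)

    def test_sampling_error_shrinks_with_n(self):
        # empirical histogram vs exact Poisson pmf: L1 error decays with n
        rng = np.random.default_rng(1)
        ref = histogram_from_pmf(np.arange(61), stats.poisson.pmf(np.arange(61), 20.0), 2)
        errs = []
        for n in (200, 20000):
            h = build_histogram(rng.poisson(20.0, n), 2)
            errs.append(l1_distance(h, ref))
        assert errs[1] < errs[0] / 3


class TestEfficiency:
    def test_value(self):
        # total error 0.5, total time 4 s: eta = 2 / 4 = 0.5
        assert efficiency([0.2, 0.3], [1.0, 3.0]) == pytest.approx(0.5)

    def test_zero_error_unbounded(self):
        assert efficiency([0.0], [1.0]) == float("inf")

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            efficiency([0.1], [0.0])


class TestWeakOrderSlope:
    def test_exact_power_law(self):
        taus = [0.4, 0.2, 0.1]
        errs = [3 * t**2 for t in taus]
        assert weak_order_slope(taus, errs) == pytest.approx(2.0)

    def test_rejects_zero_errors(self):
        with pytest.raises(ValueError):
            weak_order_slope([0.1, 0.2], [0.0, 1.0])


class TestLinearMomentOracle:
    def test_yule_values(self):
        mean, var = linear_moment_oracle(0.2, 1000, 12.0)
        g = np.exp(2.4)
        assert mean == pytest.approx(1000 * g)
        assert var == pytest.approx(1000 * g * (g - 1))

    def test_zero_time(self):
        mean, var = linear_moment_oracle(0.2, 7, 0.0)
        assert mean == 7 and var == 0


class TestCMEOracle:
    def test_three_state_decay_hand_example(self):
        # X -> 0 from x0 = 2 at unit rate: P(2) = e^{-2t}, and the mean is
        # 2 e^{-t} (each particle survives independently)
        sys = build_system(
            ["X"], [{"reactants": {"X": 1}, "products": {}, "c": 1.0}]
        )
        t = 0.4
        states, probs = cme_oracle(sys, StateVector([2]), t, truncation=2)
        assert probs.sum() == pytest.approx(1.0, abs=1e-10)
        mean = cme_mean(states, probs, 0)
        assert mean == pytest.approx(2 * np.exp(-t), abs=1e-8)
        idx2 = int(np.nonzero((states[:, 0] == 2))[0][0])
        assert probs[idx2] == pytest.approx(np.exp(-2 * t), abs=1e-8)

    def test_annihilation_against_binomial_structure(self):
        # X + Y -> 0 with X(0)=Y(0)=3: state space is v = 0..3; mass
        # conserves and mean decreases
        fx = annihilation(c=0.5, x0=3, T=1.0)
        states, probs = cme_oracle(fx.system, fx.x0, 1.0, truncation=3)
        assert probs.sum() == pytest.approx(1.0, abs=1e-10)
        assert 0 < cme_mean(states, probs, 0) < 3

    def test_truncation_leak_detected(self):
        # Yule growth truncated far too low leaks mass
        sys = build_system(
            ["X"], [{"reactants": {"X": 1}, "products": {"X": 2}, "c": 1.0}]
        )
        with pytest.raises(RuntimeError, match="leak"):
            cme_oracle(sys, StateVector([5]), 3.0, truncation=8)


class TestChainDistribution:
    def test_is_probability_distribution(self):
        fx = annihilation(c=0.004, x0=50, T=5.0)
        state_of = lambda v: np.array([v, v], dtype=np.int64)  # noqa: E731
        v, p = chain_distribution(fx.system, fx.x0, 1.0, 5.0, method="sbs",
                                  k=2, state_of=state_of, v_max=50)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(p >= 0)

    def test_tl_matches_single_step_poisson_thinning(self):
        # one tau-leap step of pure decay from x0: K ~ Poisson(x0 c tau),
        # X = x0 - K (lumped at 0)
        sys = build_system(
            ["X"], [{"reactants": {"X": 1}, "products": {}, "c": 1.0}]
        )
        x0, tau = 30, 0.1
        v, p = chain_distribution(sys, StateVector([x0]), tau, tau,
                                  method="tl", v_max=x0)
        lam = x0 * tau
        k = np.arange(0, x0 + 1)
        expect = np.zeros(x0 + 1)
        pk = stats.poisson.pmf(np.arange(0, 200), lam)
        for kk in range(200):
            expect[max(x0 - kk, 0)] += pk[kk]
        np.testing.assert_allclose(p, expect, atol=1e-10)

    def test_sbs_two_steps_mean_close_to_exact(self):
        sys = build_system(
            ["X"], [{"reactants": {"X": 1}, "products": {}, "c": 1.0}]
        )
        v, p = chain_distribution(sys, StateVector([40]), 0.5, 1.0,
                                  method="sbs", k=3, v_max=40)
        mean = float(np.dot(v, p))
        assert mean == pytest.approx(40 * np.exp(-1.0), rel=2e-3)

    def test_sbsda_distribution_valid(self):
        sys = build_system(
            ["X"], [{"reactants": {"X": 1}, "products": {}, "c": 1.0}]
        )
        v, p = chain_distribution(sys, StateVector([40]), 0.5, 1.0,
                                  method="sbsda", k=2, v_max=40)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        mean = float(np.dot(v, p))
        assert mean == pytest.approx(40 * np.exp(-1.0), rel=0.02)

    def test_rejects_off_support_x0(self):
        fx = annihilation(c=0.01, x0=5, T=1.0)
        state_of = lambda v: np.array([v, v], dtype=np.int64)  # noqa: E731
        with pytest.raises(ValueError):
            chain_distribution(fx.system, StateVector([5, 4]), 0.5, 1.0,
                               method="tl", state_of=state_of, v_max=5)

    def test_rejects_non_multiple_horizon(self):
        sys = build_system(
            ["X"], [{"reactants": {"X": 1}, "products": {}, "c": 1.0}]
        )
        with pytest.raises(ValueError):
            chain_distribution(sys, StateVector([5]), 0.3, 1.0, method="tl")
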