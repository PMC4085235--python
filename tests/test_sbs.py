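import numpy as np
import pytest

from sbskit.extrapolation import NevilleTable, neville_extend, propensity_integral, substep_count
from sbskit.model import SolverSettings, StateVector, build_system
from sbskit.reference import StepsizeUnderflowError
from sbskit.sbs import (
    candidate_stepsize,
    initial_tau,
    sbs_fixed,
    sbs_fixed_step_mean,
    sbs_simulate,
    sbs_step,
    select_column,
)


@pytest.fixture
def decay_1d():
    return build_system(
        ["X"], [{"reactants": {"X": 1}, "products": {}, "c": 1.0}]
    )


class TestCandidateStepsize:
    def test_column_two_scaling(self):
        # k=2: exponent 1/3; err = 8 S2 -> factor S1 * (1/8)^{1/3} = S1/2
        out = candidate_stepsize(1.0, 8 * 0.4, 2, S1=0.5, S2=0.4)
        assert out == pytest.approx(0.25)

    def test_small_error_grows_stepsize(self):
        out = candidate_stepsize(1.0, 0.4 / 8, 2, S1=0.5, S2=0.4)
        assert out == pytest.approx(1.0)  # S1 * 8^{1/3} = 0.5 * 2

    def test_growth_capped_at_max_growth(self):
        out = candidate_stepsize(1.0, 1e-12, 2, S1=0.5, S2=0.4, max_growth=4.0)
        assert out <= 4.0

    def test_vanishing_error_branch(self):
        out = candidate_stepsize(2.0, 0.0, 3, S1=0.5, S2=0.4, max_growth=4.0)
        assert out == pytest.approx(2.0 * 0.5 * 4.0)

    def test_remaining_clamps(self):
        out = candidate_stepsize(1.0, 0.4, 2, S1=0.9, S2=0.4, remaining=0.3)
        assert out == pytest.approx(0.3)

    def test_higher_column_less_sensitive_to_error(self):
        # same err ratio shrinks tau less at larger k (bigger root)
        t2 = candidate_stepsize(1.0, 100.0, 2, S1=0.5, S2=0.4)
        t5 = candidate_stepsize(1.0, 100.0, 5, S1=0.5, S2=0.4)
        assert t5 > t2


class TestSelectColumn:
    def test_minimises_work_per_unit_step(self):
        # W = A/tau: (2, 1.0, 7) -> 7; (3, 2.0, 13) -> 6.5: pick k=3
        assert select_column([(2, 1.0, 7), (3, 2.0, 13)]) == (3, 2.0)

    def test_tie_breaks_to_smaller_k(self):
        assert select_column([(2, 7.0, 7), (3, 13.0, 13)])[0] == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_column([])


class TestFixedStepMean:
    def test_k1_is_single_trapezoid_integral(self, decay_1d):
        x = StateVector([1000])
        lam = sbs_fixed_step_mean(decay_1d, x, 0.1, 1)
        assert lam[0] == pytest.approx(95.125)

    def test_k2_matches_manual_extrapolation(self, decay_1d):
        x = StateVector([1000])
        t = NevilleTable()
        for q in (1, 2):
            n = substep_count(q)
            neville_extend(t, propensity_integral(decay_1d, x, 0.1, n), n)
        lam = sbs_fixed_step_mean(decay_1d, x, 0.1, 2)
        assert lam[0] == pytest.approx(t.diagonal(2)[0])

    def test_clamped_non_negative(self, decay_1d):
        lam = sbs_fixed_step_mean(decay_1d, StateVector([0]), 0.1, 2)
        assert lam[0] == 0.0


class TestSbsStep:
    def test_accepted_column_error_below_one(self, chain_decay):
        settings = chain_decay.sbs_settings()
        rng = np.random.default_rng(0)
        rec, new_state, tau_star, window = sbs_step(
            chain_decay.system, chain_decay.x0, 0.5, settings, rng,
            list(range(2, settings.k_max + 1)), remaining=5.0, tau_floor=1e-12,
        )
        assert 2 <= rec.k_converged <= settings.k_max
        assert rec.tau_used <= 0.5
        assert new_state.time == pytest.approx(rec.t_start + rec.tau_used)
        assert all(2 <= q <= settings.k_max for q in window)
        assert len(window) <= 3

    def test_work_accounting(self, chain_decay):
        # work for an un-rejected step accepted at column k with one extra
        # order-increase row: sum_{q=1..k+1} (2q + 1)
        settings = chain_decay.sbs_settings()
        rng = np.random.default_rng(1)
        rec, *_ = sbs_step(
            chain_decay.system, chain_decay.x0, 0.5, settings, rng,
            list(range(2, settings.k_max + 1)), remaining=5.0, tau_floor=1e-12,
        )
        if rec.rejections == 0:
            k_top = rec.k_converged + (1 if rec.k_converged < settings.k_max else 0)
            expected = sum(2 * q + 1 for q in range(1, k_top + 1))
            assert rec.work == expected

    def test_forced_rejection_halves_tau(self):
        # impossible tolerance: no column converges, tau halves until the
        # floor trips
        sys = build_system(
            ["X"], [{"reactants": {"X": 2}, "products": {"X": 1}, "c": 0.1}]
        )
        settings = SolverSettings(S1=0.5, S2=0.4, atol=0.0, rtol=1e-300, k_max=3)
        # the floor sits just under the initial tau, so the first halving
        # trips it — proving the step was rejected rather than accepted
        with pytest.raises(StepsizeUnderflowError):
            sbs_step(
                sys, StateVector([100]), 1.0, settings,
                np.random.default_rng(2), [2, 3], remaining=1.0, tau_floor=0.9,
            )

    def test_zero_propensity_state_steps_to_horizon(self, decay_1d):
        settings = SolverSettings(S1=0.5, S2=0.4, rtol=1e-4, atol=1e-8)
        rng = np.random.default_rng(3)
        rec, new_state, *_ = sbs_step(
            decay_1d, StateVector([0]), 2.0, settings, rng,
            [2, 3], remaining=2.0, tau_floor=1e-12,
        )
        assert new_state.counts[0] == 0
        assert new_state.time == pytest.approx(2.0)


class TestInitialTau:
    def test_explicit_tau0(self, chain_decay):
        s = SolverSettings(tau0=0.25)
        assert initial_tau(chain_decay.system, chain_decay.x0, s, 5.0) == 0.25

    def test_default_multiple_of_waiting_time(self, chain_decay):
        s = SolverSettings(tau0_multiple=10.0)
        a0 = 10000.0 + 1.0
        assert initial_tau(chain_decay.system, chain_decay.x0, s, 5.0) == pytest.approx(10.0 / a0)

    def test_clamped_to_horizon(self, chain_decay):
        s = SolverSettings(tau0=100.0)
        assert initial_tau(chain_decay.system, chain_decay.x0, s, 5.0) == 5.0


class TestSbsSimulate:
    def test_chain_decay_runs_and_conserves(self, chain_decay):
        rng = np.random.default_rng(4)
        traj, records = sbs_simulate(
            chain_decay.system, chain_decay.x0, chain_decay.T,
            chain_decay.sbs_settings(), rng,
        )
        assert traj.times[-1] == pytest.approx(chain_decay.T)
        assert traj.final_state.sum() == 10001
        assert np.all(traj.final_state >= 0)
        assert sum(r.tau_used for r in records) == pytest.approx(chain_decay.T)

    def test_chain_decay_mean(self, chain_decay):
        rng = np.random.default_rng(5)
        n = 100
        finals = np.array([
            sbs_simulate(chain_decay.system, chain_decay.x0, 5.0,
                         chain_decay.sbs_settings(), rng)[0].final_state[0]
            for _ in range(n)
        ])
        expected = 10000 * np.exp(-5.0)
        se = np.sqrt(expected) / np.sqrt(n)
        assert abs(finals.mean() - expected) < 5 * se

    def test_takes_few_steps(self, chain_decay):
        rng = np.random.default_rng(6)
        _, records = sbs_simulate(
            chain_decay.system, chain_decay.x0, 5.0,
            chain_decay.sbs_settings(), rng,
        )
        # orders of magnitude fewer steps than SSA's ~20000 events
        assert len(records) < 200

    def test_seed_reproducibility(self, chain_decay):
        out = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            traj, _ = sbs_simulate(
                chain_decay.system, chain_decay.x0, 5.0,
                chain_decay.sbs_settings(), rng,
            )
            out.append(traj.final_state.copy())
        np.testing.assert_array_equal(out[0], out[1])


class TestSbsFixed:
    def test_replay_equals_poisson_with_same_stream(self, chain_decay):
        # the fixed-step chain is a Poisson draw around deterministic
        # parameters: replaying the parameter sequence with an identical RNG
        # stream reproduces the trajectory bit for bit
        sys = chain_decay.system
        tau, k, T = 0.5, 2, 5.0
        traj = sbs_fixed(sys, chain_decay.x0, T, tau, k,
                         np.random.default_rng(8))
        rng = np.random.default_rng(8)
        state = chain_decay.x0.counts.copy()
        for _ in range(round(T / tau)):
            lam = sbs_fixed_step_mean(sys, StateVector(state), tau, k)
            kk = rng.poisson(np.maximum(lam, 0.0))
            state = state + sys.effective_net_change @ kk
        np.testing.assert_array_equal(traj.final_state, state)

    def test_rejects_non_multiple_horizon(self, chain_decay):
        with pytest.raises(ValueError):
            sbs_fixed(chain_decay.system, chain_decay.x0, 5.0, 0.3, 2,
                      np.random.default_rng(9))
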