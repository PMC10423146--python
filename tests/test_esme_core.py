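import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esme import esme_core, model_zoo
from esme.crn_model import LinearSubsystem, ModulatedCRN, RateStructure
from esme.environment import explicit_environment, telegraph

from conftest import random_scalar_model


class TestBlockAssembly:
    def test_single_state_reduces_to_homogeneous(self, homogeneous_bd):
        res = esme_core.solve(homogeneous_bd)
        assert res.mean[0] == pytest.approx(10.0, rel=1e-12)
        assert np.allclose(res.x, res.y)  # pi = 1

    def test_e1_rows_match_hand_assembly(self):
        """For the telegraph-death model the two block rows are
        c3 y0 - c4 y1 = lam pi0 and -c3 y0 + (c6 + c4) y1 = lam pi1."""
        crn = model_zoo.make_e1(qss_mean=10.0, p_off=0.5, ratio=1.0)
        c3 = crn.environment.meta["rate_on"]
        c4 = crn.environment.meta["rate_off"]
        lam, c6 = crn.meta["birth"], crn.meta["c6"]
        system = esme_core.assemble_block_system(crn)
        M = system.blockA.toarray()
        assert np.allclose(M, [[c3, -c4], [-c3, c6 + c4]])
        assert np.allclose(system.rhs,
                           [lam * crn.environment.pi[0],
                            lam * crn.environment.pi[1]])

    def test_sparsity_follows_environment_generator(self):
        crn = model_zoo.make_toggle(ratio=1e-3)
        system = esme_core.assemble_block_system(crn)
        nz = crn.environment.n_states
        d = 2
        assert system.blockA.shape == (nz * d, nz * d)
        nnz_env = np.count_nonzero(crn.environment.Lambda)
        assert system.blockA.nnz <= nz * d * d + nnz_env * d


class TestSolve:
    def test_e1_symmetric_switch_solution(self):
        """With c3 = c4 = q the hand-solved 2x2 system gives
        y1 = lam/c6 and y0 = lam/c6 + lam pi0 / q."""
        crn = model_zoo.make_e1(qss_mean=10.0, p_off=0.5, ratio=0.25)
        q = crn.environment.meta["rate_on"]
        lam, c6 = crn.meta["birth"], crn.meta["c6"]
        res = esme_core.solve(crn)
        assert res.y[1, 0] == pytest.approx(lam / c6, rel=1e-12)
        assert res.y[0, 0] == pytest.approx(lam / c6 + lam * 0.5 / q,
                                            rel=1e-12)

    def test_mean_is_sum_of_weighted_conditional_means(self, e2_small):
        res = esme_core.solve(e2_small)
        assert np.allclose(res.mean, res.y.sum(axis=0), rtol=1e-10)
        assert np.allclose(res.mean,
                           (res.pi[:, None] * res.x).sum(axis=0), rtol=1e-10)

    def test_x_form_equals_y_form_under_detailed_balance(self, e2_small):
        """Birth-death environments are reversible, so the unweighted
        recursion must reproduce the weighted one."""
        assert esme_core.detailed_balance_holds(e2_small.environment)
        mean_x = esme_core.solve_x_form(e2_small)
        mean_y = esme_core.solve(e2_small).mean
        assert np.allclose(mean_x, mean_y, rtol=1e-9)

    def test_x_form_rejected_without_detailed_balance(self):
        # 3-cycle with asymmetric rates violates reversibility
        Lam = np.array([[-1.0, 0.1, 2.0],
                        [1.0, -2.1, 0.3],
                        [0.0, 2.0, -2.3]])
        env = explicit_environment([0, 1, 2], Lam)
        assert not esme_core.detailed_balance_holds(env)
        sub = LinearSubsystem(["X"], S=[[0, 1]], P=[[1, 0]])
        rates = RateStructure(Gamma=lambda z: [[0.0], [1.0 + z]],
                              gamma=lambda z: [5.0, 0.0], states=env.states)
        crn = ModulatedCRN(sub, rates, env)
        with pytest.raises(esme_core.SolveError, match="detailed.balance"):
            esme_core.solve_x_form(crn)

    def test_scalar_reduction_matches_block_solve(self, e2_small):
        reduced = esme_core.mean_d1_reduction(e2_small)
        full = esme_core.solve(e2_small).mean[0]
        assert reduced == pytest.approx(full, rel=1e-12)

    def test_zeroth_order_modulation_keeps_qss_mean(self, birth_modulated):
        """Modulating only constant-rate reactions cannot move the mean:
        it must equal the averaged-environment reference exactly."""
        res = esme_core.solve(birth_modulated)
        assert np.allclose(res.mean, res.qss_mean, rtol=1e-9)
        assert np.allclose(res.deviation, 0.0, atol=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_recursion_residual_on_random_models(self, seed):
        """The solved conditional means satisfy the per-state recursion,
        checked state by state independently of the block assembly."""
        crn = random_scalar_model(np.random.default_rng(seed))
        res = esme_core.solve(crn, check_condition=False)
        resid = esme_core.recursion_residual(crn, res.x)
        assert resid < 1e-9 * max(1.0, np.abs(res.x).max())
        assert np.allclose(res.shares.sum(axis=0), 1.0, atol=1e-10)


class TestQss:
    def test_homogeneous(self, homogeneous_bd):
        assert esme_core.qss_mean(homogeneous_bd)[0] == pytest.approx(10.0)

    def test_e2_value(self):
        crn = model_zoo.make_e2(qss_mean=10.0, env_mean=8.0, ratio=1.0)
        assert esme_core.qss_mean(crn)[0] == pytest.approx(10.0, rel=1e-9)

    def test_controller_setpoint_independent_of_env_mean(self):
        for env_mean in (0.5, 4.0, 9.0):
            crn = model_zoo.make_controller(c1=1000.0, c2=100.0,
                                            env_mean=env_mean)
            assert esme_core.qss_mean(crn)[1] == pytest.approx(10.0,
                                                               rel=1e-9)

    def test_relative_deviation(self):
        assert esme_core.relative_deviation(10.005, 10.0)[0] == \
            pytest.approx(5e-4)
        with pytest.raises(ZeroDivisionError):
            esme_core.relative_deviation(np.array([1.0]), np.array([0.0]))


class TestShares:
    def test_single_state_share_is_one(self, homogeneous_bd):
        res = esme_core.solve(homogeneous_bd)
        assert esme_core.environmental_shares(res, 0) == {0: 1.0}

    def test_shares_normalize(self, e2_small):
        res = esme_core.solve(e2_small)
        total = sum(esme_core.environmental_shares(res, 0).values())
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_slow_environment_zero_state_dominates(self):
        crn = model_zoo.make_e1(qss_mean=10.0, p_off=0.5, ratio=1e3)
        res = esme_core.solve(crn)
        assert res.share_map(0)[0] > 0.99

    def test_binned_shares_partition(self, e2_small):
        res = esme_core.solve(e2_small)
        bins = esme_core.binned_shares(res, 0)
        assert sum(bins.values()) == pytest.approx(1.0, abs=1e-10)
        assert set(bins) == {"zero", "below_mean", "at_or_above_mean"}

    def test_share_regimes_shift_with_environment_speed(self):
        """Three phases of the Poisson-modulated model: fast — the
        at-or-above-mean states dominate and the zero state is negligible;
        intermediate — the sub-mean states take the lead; slow — the zero
        state carries nearly everything."""
        bins = {}
        for ratio in (1e-3, 1e3, 1e5):
            res = esme_core.solve(model_zoo.make_e2(ratio=ratio,
                                                    tail_mass=1e-10),
                                  check_condition=False)
            bins[ratio] = esme_core.binned_shares(res, 0)
        fast, mid, slow = bins[1e-3], bins[1e3], bins[1e5]
        assert fast["zero"] < 0.01
        assert fast["at_or_above_mean"] > fast["below_mean"]
        assert mid["below_mean"] == max(mid.values())
        assert slow["zero"] > 0.9


class TestValidity:
    def test_nonnegative_models_pass_clean(self, e2_small):
        res = esme_core.solve(e2_small)
        assert res.validity.passed
        assert res.validity.flagged_states == []

    def test_toggle_inside_validity_region(self):
        res = esme_core.solve(model_zoo.make_toggle(ratio=1e-3))
        assert res.validity.passed

    def test_toggle_past_asymptote_fails(self):
        """Far past the asymptote the linearized switch stops being
        descriptive: shares go negative and the gate must fail."""
        res = esme_core.solve(model_zoo.make_toggle(ratio=2.0),
                              check_condition=False)
        assert not res.validity.passed

    def test_share_error_for_zero_mean(self):
        env = telegraph(rate_on=1.0, rate_off=1.0)
        sub = LinearSubsystem(["X"], S=[[0, 1]], P=[[1, 0]])
        rates = RateStructure(Gamma=lambda z: [[0.0], [1.0]],
                              gamma=lambda z: [0.0, 0.0], states=env.states)
        res = esme_core.solve(ModulatedCRN(sub, rates, env))
        with pytest.raises(ZeroDivisionError):
            esme_core.environmental_shares(res, 0)
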