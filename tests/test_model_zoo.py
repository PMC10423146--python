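import numpy as np
import pytest

from esme import esme_core, model_zoo
from esme.model_zoo import ZooError


class TestE1:
    def test_symmetric_switch_occupancy(self):
        crn = model_zoo.make_e1(qss_mean=10.0, p_off=0.5, ratio=1.0)
        assert np.allclose(crn.environment.pi, [0.5, 0.5])

    def test_fast_limit_mean(self):
        res = esme_core.solve(model_zoo.make_e1(10.0, 0.5, 1e-3))
        assert res.mean[0] == pytest.approx(10.005, rel=1e-10)

    def test_degenerate_switch_rejected(self):
        with pytest.raises(ZooError, match="p_off"):
            model_zoo.make_e1(10.0, 1.0, 1.0)

    def test_level_calibration_variant(self):
        """With a non-unit On level v the deviation law holds with the
        subsystem time scale (c6 v)^-1, so the solved mean is unchanged."""
        a = esme_core.solve(model_zoo.make_e1(10.0, 0.5, 0.1, level=1.0))
        b = esme_core.solve(model_zoo.make_e1(10.0, 0.5, 0.1, level=2.5))
        assert a.mean[0] == pytest.approx(b.mean[0], rel=1e-10)

    def test_explicit_birth_modulator_keeps_mean(self):
        """Re-introducing the zeroth-order birth modulator must not move
        the stationary mean (zeroth-order modulation is mean-neutral)."""
        collapsed = esme_core.solve(model_zoo.make_e1(10.0, 0.5, 0.5))
        explicit = esme_core.solve(
            model_zoo.make_e1(10.0, 0.5, 0.5, explicit_birth_modulator=True),
            check_condition=False)
        assert explicit.mean[0] == pytest.approx(collapsed.mean[0],
                                                 rel=1e-6)


class TestE2E3:
    def test_e2_leak_bounds_mean(self):
        """With a base death rate the mean saturates at birth/leak as the
        environment slows down."""
        lam0 = 0.5
        crn = model_zoo.make_e2(ratio=1e4, leak=lam0, tail_mass=1e-10)
        res = esme_core.solve(crn, check_condition=False)
        upper = crn.meta["birth"] / lam0
        assert res.mean[0] < upper
        no_leak = esme_core.solve(
            model_zoo.make_e2(ratio=1e4, tail_mass=1e-10),
            check_condition=False)
        assert no_leak.mean[0] > res.mean[0]

    def test_e2_tiny_leak_is_continuous(self):
        a = esme_core.solve(model_zoo.make_e2(ratio=1e3, tail_mass=1e-10),
                            check_condition=False).mean[0]
        b = esme_core.solve(model_zoo.make_e2(ratio=1e3, leak=1e-6,
                                              tail_mass=1e-10),
                            check_condition=False).mean[0]
        assert abs(a - b) / a < 0.01

    def test_e3_product_state_count(self):
        crn = model_zoo.make_e3(ratio=0.1, tail_mass=1e-8)
        z2_max = crn.environment.meta["z_max"]
        assert crn.environment.n_states == (z2_max + 1) * 2

    def test_e3_modulator_mean_is_exact(self):
        crn = model_zoo.make_e3(ratio=0.1, tail_mass=1e-10)
        assert crn.environment.mean(0) == pytest.approx(8.0, rel=1e-6)

    def test_e3_switch_occupancy(self):
        crn = model_zoo.make_e3(ratio=0.1, switch_on_fraction=0.8)
        assert crn.environment.mean(1) == pytest.approx(0.8, rel=1e-9)

    def test_e3_fast_switch_recovers_plain_modulator(self):
        fast = model_zoo.make_e3(ratio=0.1, switch_ratio=1000.0,
                                 tail_mass=1e-10)
        plain = model_zoo.make_e2(ratio=0.1, env_mean=8.0, tail_mass=1e-10)
        m_fast = esme_core.solve(fast, check_condition=False).mean[0]
        m_plain = esme_core.solve(plain, check_condition=False).mean[0]
        assert abs(m_fast - m_plain) / m_plain < 0.02


class TestController:
    def test_qss_components(self):
        crn = model_zoo.make_controller(c1=1000.0, c2=100.0, c5=1.0, c6=1.0,
                                        env_mean=4.0)
        qss = esme_core.qss_mean(crn)
        assert qss[0] == pytest.approx(1000.0 / 100.0 * 4.0, rel=1e-9)  # U
        assert qss[1] == pytest.approx(10.0, rel=1e-9)                  # X

    def test_zero_state_eigenvalues(self):
        crn = model_zoo.make_controller()
        report = crn.stability_report
        assert report.passed
        assert report.min_real_parts[0] == pytest.approx(0.0, abs=1e-12)

    def test_plateau_matches_closed_form(self):
        from esme.closed_forms import controller_laws
        plateau, _ = controller_laws(10.0, 1.0, 100.0, 0.01)
        assert plateau == pytest.approx(0.1)

    def test_indicator_sensing_variant_constructs(self):
        crn = model_zoo.make_controller(sensing="indicator", env_mean=4.0)
        res = esme_core.solve(crn, check_condition=False)
        assert np.all(res.mean > 0)


class TestMatching:
    def test_toggle_rates(self):
        out = model_zoo.match_qss_rates("toggle", 30.0, 25.0, 0.02, 0.02,
                                        e_z1=3.0, death_rate=0.1)
        assert out["a1"] == pytest.approx(1.5)
        assert out["a2"] == pytest.approx(43.0 / 30.0)

    def test_oscillator_rates(self):
        out = model_zoo.match_qss_rates("oscillator", 40.0, 20.0, 0.02,
                                        None, e_z1=3.0, death_rate=0.1)
        assert out["a1"] == pytest.approx(26.0 / 15.0)
        assert out["b2"] == pytest.approx(1.0 / 60.0)

    def test_symmetric_targets_give_equal_rates(self):
        out = model_zoo.match_qss_rates("toggle", 30.0, 30.0, 0.02, 0.02,
                                        e_z1=3.0, death_rate=0.1)
        assert out["a1"] == pytest.approx(out["a2"])

    def test_nonpositive_target_rejected(self):
        # matched rates are provably positive for positive targets, so the
        # feasibility gate trips on the inputs
        with pytest.raises(ZooError, match="positive"):
            model_zoo.match_qss_rates("oscillator", -1.0, 20.0, 0.02, None,
                                      e_z1=3.0, death_rate=0.1)


class TestAsymmetry:
    def test_ratios(self):
        r, r0, R = model_zoo.asymmetry_ratios([30.0, 25.0], [30.0, 25.0])
        assert (r, r0, R) == (pytest.approx(1.2), pytest.approx(1.2),
                              pytest.approx(1.0))

    def test_symmetric_switch_stays_symmetric(self):
        """A toggle with equal targets keeps R = 1 in a random
        environment at any tested speed."""
        for ratio in (1e-3, 0.1, 0.3):
            crn = model_zoo.make_toggle(x1_qss=30.0, x2_qss=30.0,
                                        ratio=ratio)
            res = esme_core.solve(crn, check_condition=False)
            _, _, R = model_zoo.asymmetry_ratios(res.mean, res.qss_mean)
            assert R == pytest.approx(1.0, abs=1e-6)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            model_zoo.asymmetry_ratios([1.0, 0.0], [1.0, 1.0])


class TestZooInvariants:
    @pytest.mark.parametrize("name, kwargs", [
        ("e1", {"ratio": 0.1}),
        ("e2", {"ratio": 0.1, "tail_mass": 1e-8}),
        ("e3", {"ratio": 0.1, "tail_mass": 1e-8}),
        ("controller", {}),
        ("toggle", {"ratio": 1e-3}),
        ("oscillator", {"ratio": 1e-3}),
    ])
    def test_constructors_pass_stability_and_environment_checks(self, name,
                                                                kwargs):
        crn = model_zoo.ZOO[name](**kwargs)
        assert crn.stability_report.passed
        env = crn.environment
        assert np.allclose(env.Lambda.sum(axis=0), 0.0,
                           atol=1e-9 * max(1.0, np.abs(env.Lambda).max()))
        assert np.abs(env.Lambda @ env.pi).max() < \
            1e-10 * max(1.0, np.abs(env.Lambda).max())

    @pytest.mark.parametrize("name, kwargs", [
        ("e1", {}),
        ("e2", {"tail_mass": 1e-8}),
        ("e3", {"tail_mass": 1e-8}),
    ])
    def test_deviation_vanishes_in_fast_environment(self, name, kwargs):
        """The Q.SS approximation becomes exact as the death modulator
        speeds up: the deviation at ratio 1e-4 is at least 5x smaller
        than at 1e-3."""
        devs = []
        for ratio in (1e-3, 1e-4):
            crn = model_zoo.ZOO[name](ratio=ratio, **kwargs)
            res = esme_core.solve(crn, check_condition=False)
            devs.append(np.abs(res.deviation).max())
        assert devs[1] <= devs[0] / 5.0

    @pytest.mark.parametrize("name", ["toggle", "oscillator"])
    def test_circuit_deviation_shrinks_with_faster_death_modulator(self,
                                                                   name):
        """For the two-species circuits only Z2 accelerates with the ratio
        while the expression modulator Z1 keeps its own (fixed, fast) time
        scale, so the deviation shrinks but retains a small Z1-induced
        floor rather than vanishing at the 5x rate of the scalar models."""
        devs = []
        for ratio in (1e-3, 1e-4):
            res = esme_core.solve(model_zoo.ZOO[name](ratio=ratio),
                                  check_condition=False)
            devs.append(np.abs(res.deviation))
        assert np.all(devs[1] < devs[0])

    @pytest.mark.parametrize("name", ["e1", "e2", "e3"])
    def test_death_modulated_deviation_is_nonnegative(self, name):
        kwargs = {} if name == "e1" else {"tail_mass": 1e-8}
        for ratio in (1e-3, 0.1, 1.0, 10.0):
            crn = model_zoo.ZOO[name](ratio=ratio, **kwargs)
            res = esme_core.solve(crn, check_condition=False)
            assert res.deviation[0] >= -1e-12
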