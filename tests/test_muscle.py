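"""Hill-type muscle model: passive curve, activation dynamics, torques."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from armreach import Muscles, PassiveForceParams, elongation_work, passive_force
from armreach.config import SCENARIO_ORDER, SCENARIOS
from armreach.muscle import severity_order


class TestPassiveForce:
    def test_below_slack_length_is_zero(self):
        p = PassiveForceParams.from_scenario("A")
        assert passive_force(p, 1.05) == 0.0

    @pytest.mark.parametrize("label", list(SCENARIOS))
    def test_continuous_at_slack_point(self, label):
        p = PassiveForceParams.from_scenario(label)
        assert passive_force(p, p.l_p) == 0.0
        assert passive_force(p, p.l_p + 1e-12) == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_values(self):
        # evaluated to high precision from s_p (exp(r_p (lbar - l_p)) - 1)
        assert passive_force(PassiveForceParams(0.05, 5, 1.1), 1.3) == \
            pytest.approx(0.0859140914, abs=1e-9)
        assert passive_force(PassiveForceParams(0.075, 8, 1.0), 1.2) == \
            pytest.approx(0.0750 * (np.e**1.6 - 1.0), abs=1e-12)
        assert passive_force(PassiveForceParams(0.075, 8, 1.0), 1.2) == \
            pytest.approx(0.296477, abs=1e-6)

    @pytest.mark.parametrize("label", list(SCENARIOS))
    def test_nonnegative_and_monotone(self, label):
        p = PassiveForceParams.from_scenario(label)
        lbar = np.linspace(0.7, 1.5, 400)
        f = passive_force(p, lbar)
        assert np.all(f >= 0)
        assert np.all(np.diff(f) >= 0)
        above = lbar > p.l_p
        assert np.all(np.diff(f[above]) > 0)

    def test_conservative_over_closed_length_loop(self):
        p = PassiveForceParams.from_scenario("H")
        up, _ = quad(lambda l: passive_force(p, l), 1.0, 1.25)
        down, _ = quad(lambda l: passive_force(p, l), 1.25, 1.0)
        assert up + down == pytest.approx(0.0, abs=1e-12)

    def test_no_passive_scenario_zero_everywhere_feasible(self, muscles):
        p = PassiveForceParams.from_scenario("no_passive")
        lmax = muscles.max_normalized_length()
        assert lmax < 1.26 < p.l_p
        lbar = np.linspace(0.7, lmax, 500)
        assert np.all(passive_force(p, lbar) == 0.0)


class TestElongationWork:
    def test_no_passive_zero(self, muscles):
        p = PassiveForceParams.from_scenario("no_passive")
        assert elongation_work(p, muscles.max_normalized_length()) == 0.0

    def test_against_quadrature(self):
        for label in ("A", "E", "H"):
            p = PassiveForceParams.from_scenario(label)
            for lmax in (1.15, 1.26):
                expected, _ = quad(lambda l: passive_force(p, l), p.l_p,
                                   max(p.l_p, lmax))
                assert elongation_work(p, lmax) == pytest.approx(expected, abs=1e-10)

    def test_scenario_a_printed_range_value(self):
        # quadrature oracle of the closed form at lbar_max = 1.26
        p = PassiveForceParams.from_scenario("A")
        assert elongation_work(p, 1.26) == pytest.approx(0.0042549, abs=2e-6)

    def test_severity_ordering_a_through_h(self, muscles):
        """Elongation work at the model's computed maximum normalized
        length orders the ageing scenarios strictly A < B < ... < H."""
        lmax = muscles.max_normalized_length()
        works = [elongation_work(PassiveForceParams.from_scenario(s), lmax)
                 for s in SCENARIO_ORDER]
        assert np.all(np.diff(works) > 0)
        assert severity_order(lmax) == SCENARIO_ORDER


class TestMuscleGeometry:
    def test_max_normalized_length_below_bound(self, muscles):
        assert muscles.max_normalized_length(200) < 1.26

    def test_random_configurations_stay_below_sweep_maximum(self, muscles, feasible_q):
        per_joint = muscles.max_normalized_length(200)
        for q in feasible_q:
            _, lbar = muscles.muscle_length(q)
            assert np.all(lbar <= per_joint + 1e-12)

    def test_antagonists_have_opposite_length_gradients(self, muscles, arm):
        h = 1e-6
        q = arm.q_init + np.array([0.2, -0.1, 0.1])
        for j in range(3):
            e = np.zeros(3)
            e[j] = h
            _, lp = muscles.muscle_length(q + e)
            _, lm = muscles.muscle_length(q - e)
            dflex = (lp - lm)[2 * j] / (2 * h)
            dext = (lp - lm)[2 * j + 1] / (2 * h)
            assert dflex * dext < 0

    def test_moment_arm_is_minus_length_gradient(self, muscles, arm):
        """Virtual work: moment arm equals -dl/dq of the muscle's joint."""
        h = 1e-6
        q = arm.q_init.copy()
        for i in range(6):
            j = muscles.joint_of_muscle[i]
            e = np.zeros(3)
            e[j] = h
            lp, _ = muscles.muscle_length(q + e)
            lm, _ = muscles.muscle_length(q - e)
            dl_dq = (lp[i] - lm[i]) / (2 * h)
            assert muscles.moment_arm(i) == pytest.approx(-dl_dq, rel=1e-6)

    def test_initial_posture_at_optimal_length(self, muscles, arm):
        _, lbar = muscles.muscle_length(arm.q_init)
        np.testing.assert_allclose(lbar, 1.0, atol=1e-12)


class TestTotalForce:
    def test_passive_only_below_slack(self):
        m = Muscles(scenario="A")
        assert m.total_force(0, l_bar=1.05, l_bar_dot=0.0, a=0.0) == 0.0

    def test_isometric_optimum_gives_fmax(self, muscles):
        for i in range(6):
            assert muscles.total_force(i, 1.0, 0.0, 1.0) == \
                pytest.approx(muscles.f_max[i], rel=1e-12)

    def test_composition_with_active_curve(self):
        m = Muscles(scenario="A")
        fa = m.active_scaling(1.3, 0.0)
        expected = m.f_max[0] * (0.5 * fa + 0.0859140914)
        assert m.total_force(0, 1.3, 0.0, 0.5) == pytest.approx(expected, rel=1e-9)

    def test_rejects_activation_out_of_range(self, muscles):
        with pytest.raises(ValueError):
            muscles.total_force(0, 1.0, 0.0, 1.5)

    def test_force_velocity_normalization(self, muscles):
        assert muscles.force_velocity(0.0) == pytest.approx(1.0)
        assert muscles.active_scaling(1.0, 0.0) == pytest.approx(1.0)
        # eccentric above isometric, concentric below
        assert muscles.force_velocity(1.0) > 1.0
        assert muscles.force_velocity(-1.0) < 1.0


class TestJointTorques:
    def test_zero_activation_no_passive_gives_zero(self, muscles, arm):
        tau = muscles.joint_torques(arm.q_init + 0.3, np.zeros(3), np.zeros(6))
        np.testing.assert_allclose(tau, 0.0, atol=1e-12)

    def test_scenario_h_restores_toward_initial_posture(self, arm):
        """With l_p = 1.0, any posture away from the initial angles evokes
        passive force pulling the elongated muscles back."""
        m = Muscles(scenario="H")
        dq = np.array([0.3, -0.2, 0.2])
        tau = m.joint_torques(arm.q_init + dq, np.zeros(3), np.zeros(6))
        assert np.all(tau * dq < 0)

    def test_balanced_antagonists_cancel(self, arm):
        """Equal activation of a symmetric pair at optimum length gives
        zero net torque (forces x arms match)."""
        m = Muscles(scenario="no_passive")
        a = np.zeros(6)
        a[0] = a[1] = 0.4
        tau = m.joint_torques(arm.q_init, np.zeros(3), a)
        np.testing.assert_allclose(tau, 0.0, atol=1e-10)


class TestActivationDynamics:
    def test_zero_fixed_point(self, muscles):
        chain = np.zeros(3)
        for _ in range(100):
            chain, a = muscles.activation_step(chain, 0.0, 1e-3)
        assert a == 0.0

    def test_step_response_monotone_bounded(self, muscles):
        chain = np.zeros(3)
        prev = 0.0
        for _ in range(3000):
            chain, a = muscles.activation_step(chain, 1.0, 1e-3)
            assert prev - 1e-12 <= a <= 1.0
            prev = a
        assert a == pytest.approx(1.0, abs=1e-2)

    def test_rejects_bad_dt(self, muscles):
        with pytest.raises(ValueError):
            muscles.activation_step(np.zeros(3), 0.5, 0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_bounded_for_arbitrary_excitation_steps(self, us):
        m = Muscles(scenario="no_passive")
        chain = np.zeros(3)
        for u in us:
            for _ in range(7):
                chain, a = m.activation_step(chain, u, 2e-3)
                assert -1e-12 <= a <= 1.0 + 1e-12
                assert np.all(chain >= -1e-12) and np.all(chain <= 1.0 + 1e-12)
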