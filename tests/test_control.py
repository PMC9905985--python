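"""Predictive PD controller: prediction, torque computation, excitation
inversion under the no-co-excitation rule."""

import numpy as np
import pytest

from armreach import ControlParams, Muscles, Simulator
from armreach.control import control_step, predict_state, torques_to_excitations


@pytest.fixture(scope="module")
def P(sim_no_passive):
    return sim_no_passive._P


@pytest.fixture(scope="module")
def x_rest(sim_no_passive):
    return sim_no_passive.initial_state()


class TestControlParams:
    def test_exactly_seven_scalars(self):
        cp = ControlParams(kp=np.ones(3), kd=np.ones(3), n_pred=5)
        assert cp.as_vector().shape == (7,)

    def test_rejects_negative_gains(self):
        with pytest.raises(ValueError):
            ControlParams(kp=np.array([-1.0, 0, 0]), kd=np.zeros(3), n_pred=0)

    def test_prediction_time_quantized_to_control_step(self):
        cp = ControlParams(kp=np.zeros(3), kd=np.zeros(3), n_pred=7)
        assert cp.t_pred(1e-3) == pytest.approx(7e-3)
        assert isinstance(cp.n_pred, int)

    def test_round_trip_json(self, tmp_path):
        cp = ControlParams(kp=np.array([1.0, 2.0, 3.0]),
                           kd=np.array([0.1, 0.2, 0.3]), n_pred=9,
                           provenance={"seed": 1})
        cp.save(tmp_path / "cp.json")
        back = ControlParams.load(tmp_path / "cp.json")
        assert back == cp
        assert back.provenance["seed"] == 1


class TestPredictState:
    def test_zero_horizon_is_identity(self, x_rest, P):
        out = predict_state(x_rest, np.zeros(6), 0, 1e-3, P)
        np.testing.assert_array_equal(out, x_rest)

    def test_matches_simulator_integration(self, x_rest, P):
        """Ballistic prediction agrees with the simulator integrating the
        same interval at its own finer substeps."""
        from armreach import _core
        x = x_rest.copy()
        x[3:6] = [0.5, -0.3, 0.2]
        pred = predict_state(x, np.zeros(6), 20, 1e-3, P)
        fine = _core.rk4(x, np.zeros(6), 1e-3 / 8, 160, P)
        np.testing.assert_allclose(pred, fine, atol=1e-8)

    def test_error_grows_with_horizon(self, x_rest, P):
        x = x_rest.copy()
        x[3:6] = [1.0, 0.5, -0.5]
        u = np.full(6, 0.3)
        errs = []
        for n in (5, 20, 40):
            pred = predict_state(x, np.zeros(6), n, 1e-3, P)
            truth = predict_state(x, u, n, 1e-3, P)  # actual future excitation
            errs.append(np.linalg.norm(pred - truth))
        assert errs[0] < errs[1] < errs[2]

    def test_rejects_negative_horizon(self, x_rest, P):
        with pytest.raises(ValueError):
            predict_state(x_rest, np.zeros(6), -1, 1e-3, P)


class TestControlStep:
    def test_zero_error_at_rest_gives_zero_torque(self, arm, x_rest):
        cp = ControlParams(kp=np.full(3, 100.0), kd=np.full(3, 10.0), n_pred=0)
        tau = control_step(arm, x_rest, arm.q_init, np.zeros(3), np.zeros(3), cp)
        np.testing.assert_allclose(tau, 0.0, atol=1e-12)

    def test_pd_sign_convention(self, arm, x_rest):
        cp = ControlParams(kp=np.full(3, 100.0), kd=np.zeros(3), n_pred=0)
        qr = arm.q_init + np.array([0.1, 0.0, 0.0])
        tau = control_step(arm, x_rest, qr, np.zeros(3), np.zeros(3), cp)
        assert tau[0] > 0  # positive position error -> flexion torque demand

    def test_feedforward_reproduces_reference_acceleration(self, arm, x_rest):
        """Gains zero: desired torque through forward dynamics returns the
        reference acceleration (round trip with the arm model)."""
        from armreach import JointState
        cp = ControlParams(kp=np.zeros(3), kd=np.zeros(3), n_pred=0)
        qr = arm.q_init
        qddr = np.array([2.0, -1.0, 0.5])
        tau = control_step(arm, x_rest, qr, np.zeros(3), qddr, cp)
        qdd = arm.forward_dynamics(JointState(q=qr, qdot=np.zeros(3)), tau,
                                   include_limits=False)
        np.testing.assert_allclose(qdd, qddr, atol=1e-9)


class TestExcitationInversion:
    def test_zero_torque_at_rest_no_passive(self, muscles, x_rest):
        u = torques_to_excitations(muscles, x_rest, np.zeros(3))
        np.testing.assert_array_equal(u, np.zeros(6))

    def test_no_co_excitation_for_any_demand(self, muscles, x_rest):
        rng = np.random.default_rng(5)
        for _ in range(200):
            tau = rng.normal(0, 20, 3)
            x = x_rest.copy()
            x[0:3] += rng.normal(0, 0.3, 3)
            x[3:6] = rng.normal(0, 1, 3)
            u = torques_to_excitations(muscles, x, tau)
            assert np.all(u >= 0.0) and np.all(u <= 1.0)
            for j in range(3):
                assert u[2 * j] * u[2 * j + 1] == 0.0

    def test_realizes_moderate_torque_demand(self, muscles, x_rest):
        """The excited agonist alone reproduces the demanded torque at the
        operating point (static check, no lag compensation)."""
        tau = np.array([3.0, -2.0, 0.5])
        u = torques_to_excitations(muscles, x_rest, tau)
        tau_back = muscles.joint_torques(x_rest[0:3], x_rest[3:6], u)
        np.testing.assert_allclose(tau_back, tau, rtol=1e-9)

    def test_saturates_at_unreachable_demand(self, muscles, x_rest):
        u = torques_to_excitations(muscles, x_rest, np.array([1e5, 0.0, 0.0]))
        assert u[0] == 1.0 and u[1] == 0.0

    def test_passive_antagonist_raises_agonist_excitation(self, x_rest, cfg):
        """At an elongated posture under the stiffest scenario, holding a
        flexion torque needs more agonist drive than without passive force
        (the passive antagonist torque must be overcome)."""
        m_h = Muscles(cfg, "H")
        m_np = Muscles(cfg, "no_passive")
        x = x_rest.copy()
        x[0] += 0.8  # shoulder flexed well past the initial angle
        tau = np.array([1.0, 0.0, 0.0])
        u_h = torques_to_excitations(m_h, x, tau)
        u_np = torques_to_excitations(m_np, x, tau)
        assert u_h[0] > u_np[0]

    def test_rejects_non_finite_demand(self, muscles, x_rest):
        with pytest.raises(ValueError):
            torques_to_excitations(muscles, x_rest, np.array([np.nan, 0, 0]))
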