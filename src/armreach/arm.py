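"""Rigid-body kinematics and dynamics of the planar three-joint arm.

The arm is a chain of three moving segments (upper arm, forearm, hand)
hinged at shoulder, elbow and wrist, moving in the horizontal plane (no
in-plane gravity torques).  The shoulder sits at the origin and the fixed
upper chest extends along the negative x axis.  Angles are counter-
clockwise, flexion positive; q[0] is the absolute upper-arm angle from the
+x axis, q[1] and q[2] are relative elbow/wrist flexions.

Equations of motion are the closed-form Lagrangian terms of a planar
3-link chain, M(q) qdd + C(q, qd) qd = tau, evaluated in the compiled
kernels (:mod:`armreach._core`); range limits are enforced by a stiff
one-sided penalty torque with damping engaged only beyond the limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _core
from .config import ModelConfig, default_config


def _check_q(q) -> np.ndarray:
    q = np.asarray(q, dtype=np.float64)
    if q.shape != (3,):
        raise ValueError("q must have three entries")
    if not np.all(np.isfinite(q)):
        raise ValueError("q must be finite")
    return q


@dataclass(frozen=True)
class JointState:
    """Joint angles (rad) and angular velocities (rad/s)."""

    q: np.ndarray
    qdot: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "q", _check_q(self.q))
        qd = np.asarray(self.qdot, dtype=np.float64)
        if qd.shape != (3,) or not np.all(np.isfinite(qd)):
            raise ValueError("qdot must be three finite entries")
        object.__setattr__(self, "qdot", qd)


class Arm:
    """Planar arm bound to one configuration.

    Parameters
    ----------
    config : ModelConfig, optional
        Full model configuration; defaults to the package defaults.
    """

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or default_config()
        self._P = self.config.pack("no_passive")
        self.L = self._P[0][0]
        self.joint_limits_lower = self._P[0][4]
        self.joint_limits_upper = self._P[0][5]
        self.q_init = np.asarray(self.config.geometry.initial_joint_angles, dtype=np.float64)

    # -- kinematics --------------------------------------------------------

    def forward_kinematics(self, q):
        """Endpoint (x, y) in metres: the distal tip of the hand segment."""
        q = _check_q(q)
        return np.array(_core.fk(q, self.L))

    def segment_frames(self, q):
        """Per-segment (origin, absolute angle) frames, proximal to distal."""
        q = _check_q(q)
        th = np.cumsum(q)
        origins = [np.zeros(2)]
        for j in range(2):
            origins.append(origins[-1] + self.L[j] * np.array([np.cos(th[j]), np.sin(th[j])]))
        return [(o, t) for o, t in zip(origins, th)]

    def endpoint_jacobian(self, q):
        """2x3 matrix mapping joint velocities to endpoint velocity."""
        return _core.jacobian(_check_q(q), self.L)

    # -- dynamics ----------------------------------------------------------

    def mass_matrix(self, q):
        M, _ = _core.mass_bias(_check_q(q), np.zeros(3), self._P[0], self._P[1])
        return M

    def bias_vector(self, q, qdot):
        """Coriolis/centrifugal generalized forces C(q, qd) qd."""
        _, h = _core.mass_bias(_check_q(q), np.asarray(qdot, float), self._P[0], self._P[1])
        return h

    def inverse_dynamics(self, q, qdot, qdd_desired):
        """Joint torques realizing qdd_desired (limit torques excluded)."""
        q = _check_q(q)
        qdot = np.asarray(qdot, dtype=np.float64)
        qdd = np.asarray(qdd_desired, dtype=np.float64)
        if not (np.all(np.isfinite(qdot)) and np.all(np.isfinite(qdd))):
            raise ValueError("qdot/qdd must be finite")
        return _core.inverse_dynamics(q, qdot, qdd, self._P[0], self._P[1])

    def forward_dynamics(self, state: JointState, joint_torques, include_limits: bool = True):
        """Angular accelerations from applied joint torques."""
        tau = np.asarray(joint_torques, dtype=np.float64)
        if tau.shape != (3,) or not np.all(np.isfinite(tau)):
            raise ValueError("joint_torques must be three finite entries")
        M, h = _core.mass_bias(state.q, state.qdot, self._P[0], self._P[1])
        if include_limits:
            tau = tau + _core.limit_torque(state.q, state.qdot, self._P[0], self._P[8])
        return np.linalg.solve(M, tau - h)

    def limit_torques(self, q, qdot):
        """One-sided joint-limit penalty torques (zero inside the limits)."""
        return _core.limit_torque(_check_q(q), np.asarray(qdot, float), self._P[0], self._P[8])

    def kinetic_energy(self, state: JointState) -> float:
        M = self.mass_matrix(state.q)
        return 0.5 * float(state.qdot @ M @ state.qdot)

    @property
    def reach_length(self) -> float:
        """Maximum endpoint distance from the shoulder (straight arm)."""
        return float(np.sum(self.L))
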