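"""Predictive PD control with inverse-dynamics feedforward.

The controller runs at a fixed rate with zero-order-hold excitations.  At
each step it (i) forward-simulates the model's own dynamics over the
prediction time t_pred holding the current excitations (noise-free
internal forward model), (ii) forms the desired joint torque as the
inverse-dynamics feedforward along the joint-space reference plus a PD
correction on the predicted tracking error, and (iii) inverts the desired
torques to muscle excitations under the no-co-excitation rule: per joint,
at most one of flexor/extensor is excited at any control step, the torque
already produced passively is subtracted first, and a first-order lead
compensates the activation lag.

The endpoint reference is converted to a joint-space reference once per
reach by damped-least-squares differential inverse kinematics of the
planned path (see :func:`joint_reference`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _core
from .plan import ReachPlan


@dataclass(frozen=True)
class ControlParams:
    """The seven tuned controller scalars.

    kp/kd are per-joint PD gains (N m/rad, N m s/rad); n_pred is the
    prediction time expressed as an integer number of control steps, so
    t_pred = n_pred * dt is quantized to the control rate.
    """

    kp: np.ndarray
    kd: np.ndarray
    n_pred: int
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        kp = np.asarray(self.kp, dtype=np.float64)
        kd = np.asarray(self.kd, dtype=np.float64)
        if kp.shape != (3,) or kd.shape != (3,):
            raise ValueError("kp and kd must each have three entries")
        if np.any(kp < 0) or np.any(kd < 0) or self.n_pred < 0:
            raise ValueError("gains and n_pred must be non-negative")
        object.__setattr__(self, "kp", kp)
        object.__setattr__(self, "kd", kd)
        object.__setattr__(self, "n_pred", int(self.n_pred))

    def __eq__(self, other):
        if not isinstance(other, ControlParams):
            return NotImplemented
        return bool(np.array_equal(self.as_vector(), other.as_vector()))

    def __hash__(self):
        return hash(tuple(self.as_vector()))

    def t_pred(self, dt: float) -> float:
        return self.n_pred * dt

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.kp, self.kd, [self.n_pred]])

    @classmethod
    def from_vector(cls, v, provenance=None) -> "ControlParams":
        v = np.asarray(v, dtype=np.float64)
        return cls(kp=v[0:3], kd=v[3:6], n_pred=int(round(v[6])),
                   provenance=provenance or {})

    def save(self, path: str | Path) -> None:
        payload = {
            "kp": self.kp.tolist(),
            "kd": self.kd.tolist(),
            "n_pred": self.n_pred,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ControlParams":
        payload = json.loads(Path(path).read_text())
        return cls(kp=np.array(payload["kp"]), kd=np.array(payload["kd"]),
                   n_pred=int(payload["n_pred"]),
                   provenance=payload.get("provenance", {}))


def goal_configuration(arm, target, n_starts: int = 8) -> np.ndarray:
    """A feasible configuration whose endpoint is (as close as possible
    to) the target, preferring solutions near the initial posture.

    Deterministic multi-start damped Gauss-Newton with projection onto
    the joint box: starts at the initial posture plus a fixed fan of
    postures spanning the shoulder range.  Used to steer the redundancy
    of the reference IK onto the correct configuration branch.
    """
    target = np.asarray(target, dtype=np.float64)
    lo, hi = arm.joint_limits_lower, arm.joint_limits_upper
    starts = [arm.q_init.copy()]
    for f in np.linspace(0.05, 0.95, n_starts - 1):
        starts.append(lo + f * (hi - lo))
    best_q, best_err, best_score = None, np.inf, np.inf
    for q0 in starts:
        q = q0.copy()
        for _ in range(200):
            r = target - arm.forward_kinematics(q)
            if r @ r < 1e-20:
                break
            J = arm.endpoint_jacobian(q)
            JJt = J @ J.T + 1e-6 * np.eye(2)
            q = np.clip(q + J.T @ np.linalg.solve(JJt, r), lo, hi)
        err = float(np.linalg.norm(target - arm.forward_kinematics(q)))
        score = err * 1e3 + 0.1 * float(np.linalg.norm(q - arm.q_init))
        if score < best_score - 1e-12:
            best_q, best_err, best_score = q, err, score
    return best_q


def joint_reference(arm, plan: ReachPlan, dt: float,
                    k_fb: float = 50.0, lam: float = 0.01,
                    k_null: float = 2.0):
    """Joint-space reference (q, qd, qdd) tracking the planned path.

    Differential inverse kinematics with damped least squares, endpoint
    feedback and a nullspace bias toward mid-range joint angles (which
    keeps the reference off the joint limits), integrated at the control
    rate from the initial posture; velocities and accelerations by
    central differences.  Beyond the plan the reference holds the final
    posture at rest.
    """
    q_goal = goal_configuration(arm, plan.target)
    from .plan import minimum_jerk
    w_goal = minimum_jerk(plan.times / plan.duration)
    qr = _core.ik_reference(
        np.ascontiguousarray(plan.position), np.ascontiguousarray(plan.velocity),
        np.ascontiguousarray(w_goal), arm.q_init.copy(), q_goal, arm.L,
        arm.joint_limits_lower, arm.joint_limits_upper, dt, k_fb, lam,
        k_null)
    # The endpoint path holds the target through the homing window; the
    # IK's own feedback makes the joint reference settle exponentially
    # onto a feasible target posture there, so it is used as-is.
    qdr = np.gradient(qr, dt, axis=0)
    qddr = np.gradient(qdr, dt, axis=0)
    return qr, qdr, qddr


def predict_state(x, u, n_pred: int, dt: float, P):
    """Forward-simulate the model's own dynamics over n_pred control steps
    holding excitations u; n_pred = 0 returns the state unchanged."""
    if n_pred < 0:
        raise ValueError("n_pred must be >= 0")
    x = np.asarray(x, dtype=np.float64)
    if n_pred == 0:
        return x.copy()
    return _core.rk4(x, np.asarray(u, dtype=np.float64), dt, n_pred, P)


def control_step(arm, x_pred, qr, qdr, qddr, cp: ControlParams):
    """Desired joint torques: inverse-dynamics feedforward along the
    reference plus PD correction on the (predicted) tracking error."""
    tau_ff = arm.inverse_dynamics(qr, qdr, qddr)
    e = qr - x_pred[0:3]
    ed = qdr - x_pred[3:6]
    return tau_ff + cp.kp * e + cp.kd * ed


def torques_to_excitations(muscles, x_pred, tau_des, c_lag: float = 0.0):
    """Muscle excitations in [0, 1] realizing tau_des; no co-excitation.

    Unreachable demands (beyond capacity at u = 1) saturate at 1.
    """
    tau_des = np.asarray(tau_des, dtype=np.float64)
    if not np.all(np.isfinite(tau_des)):
        raise ValueError("tau_des must be finite")
    return _core.excitations_from_torques(
        np.asarray(x_pred, dtype=np.float64), tau_des, c_lag, muscles._P)
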