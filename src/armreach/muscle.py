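"""Hill-type muscle mechanics.

Each of the six muscles (flexor/extensor pair per joint) produces

    f_tot(l, ldot, t) = f_max [ f_a(l, ldot) a(t) + f_p(l) ]

where f_a is the active force-length-velocity scaling (Gaussian
force-length times a Hill-type force-velocity factor), a(t) the activation
state from a third-order excitation-to-activation chain, and f_p the
exponential passive element

    f_p(lbar) = s_p (exp(r_p (lbar - l_p)) - 1)   for lbar > l_p, else 0

with lbar = l / l_0 the normalized muscle length.  The passive curve is
identical for all muscles within a scenario; absolute passive forces
differ only through f_max and each muscle's length excursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _core
from .config import SCENARIOS, ModelConfig, default_config


@dataclass(frozen=True)
class PassiveForceParams:
    """Parameters (s_p, r_p, l_p) of one scenario's passive curve."""

    s_p: float
    r_p: float
    l_p: float

    def __post_init__(self):
        if self.s_p < 0 or self.r_p <= 0 or self.l_p <= 0:
            raise ValueError("require s_p >= 0, r_p > 0, l_p > 0")

    @classmethod
    def from_scenario(cls, label: str) -> "PassiveForceParams":
        return cls(*SCENARIOS[label])


@dataclass
class MuscleState:
    """State of one muscle: length, rate, activation chain, total force."""

    l: float
    l_dot: float
    l_bar: float
    a: float
    chain: np.ndarray = field(default_factory=lambda: np.zeros(3))
    f_tot: float = 0.0


def passive_force(p: PassiveForceParams, l_bar):
    """Dimensionless passive force f_p(lbar); zero at and below l_p."""
    l_bar = np.asarray(l_bar, dtype=np.float64)
    out = np.where(
        l_bar > p.l_p,
        p.s_p * (np.exp(p.r_p * (l_bar - p.l_p)) - 1.0),
        0.0,
    )
    return float(out) if out.ndim == 0 else out


def elongation_work(p: PassiveForceParams, l_bar_max: float) -> float:
    """Work (dimensionless, per f_max*l_0) to stretch from l_p to l_bar_max.

    Closed form of the integral of f_p over normalized length:
    s_p [ (exp(r_p d) - 1)/r_p - d ],  d = l_bar_max - l_p  (0 if d <= 0).
    """
    d = l_bar_max - p.l_p
    if d <= 0:
        return 0.0
    return p.s_p * ((np.exp(p.r_p * d) - 1.0) / p.r_p - d)


class Muscles:
    """The six muscles of one configuration, under one passive scenario."""

    NAMES = ["sh_flex", "sh_ext", "el_flex", "el_ext", "wr_flex", "wr_ext"]

    def __init__(self, config: ModelConfig | None = None,
                 scenario: str | PassiveForceParams = "no_passive"):
        self.config = config or default_config()
        if isinstance(scenario, PassiveForceParams):
            self.passive = scenario
            self.scenario_label = "custom"
        else:
            self.passive = PassiveForceParams.from_scenario(scenario)
            self.scenario_label = scenario
        self._P = self.config.pack((self.passive.s_p, self.passive.r_p, self.passive.l_p))
        m = self.config.muscles
        self.f_max = np.asarray(m.f_max, float)
        self.l_0 = np.asarray(m.l_0, float)
        self.moment_arms = np.asarray(m.moment_arm, float)
        self.joint_of_muscle = np.asarray(m.joint_of_muscle, int)
        self.q_init = np.asarray(self.config.geometry.initial_joint_angles, float)

    # -- geometry ----------------------------------------------------------

    def muscle_length(self, q, qdot=None):
        """(l, lbar) for all six muscles; also (ldot, lbardot) if qdot given."""
        q = np.asarray(q, float)
        qd = np.zeros(3) if qdot is None else np.asarray(qdot, float)
        lbar, lbardot = _core.muscle_kinematics(
            q, qd, self._P[3], self._P[4], self._P[5], self._P[6])
        l = lbar * self.l_0
        if qdot is None:
            return l, lbar
        return l, lbar, lbardot * self.l_0, lbardot

    def moment_arm(self, i: int, q=None) -> float:
        """Signed moment arm (m) of muscle i; equals -dl/dq of its joint."""
        return float(self.moment_arms[i])

    # -- force generation --------------------------------------------------

    def force_length(self, l_bar):
        g = self.config.muscles.gamma_fl
        return np.exp(-((np.asarray(l_bar, float) - 1.0) ** 2) / g)

    def force_velocity(self, l_bar_dot):
        misc = self._P[8]
        arr = np.atleast_1d(np.asarray(l_bar_dot, float))
        out = np.array([_core.force_velocity(v, misc) for v in arr])
        return float(out[0]) if np.isscalar(l_bar_dot) or np.ndim(l_bar_dot) == 0 else out

    def active_scaling(self, l_bar, l_bar_dot):
        """f_a(l, ldot): normalized active force scaling, f_a(1, 0) = 1."""
        return self.force_length(l_bar) * self.force_velocity(l_bar_dot)

    def total_force(self, i: int, l_bar: float, l_bar_dot: float, a: float):
        """Total force (N) of muscle i; non-negative (muscles only pull)."""
        if not 0.0 <= a <= 1.0:
            raise ValueError("activation a must be within [0, 1]")
        fa = self.active_scaling(l_bar, l_bar_dot)
        fp = passive_force(self.passive, l_bar)
        return max(float(self.f_max[i] * (fa * a + fp)), 0.0)

    def joint_torques(self, q, qdot, activations):
        """Net joint torques (3,) from all six muscles at the given state."""
        f = _core.muscle_forces(
            np.asarray(q, float), np.asarray(qdot, float),
            np.asarray(activations, float),
            self._P[2], self._P[3], self._P[4], self._P[5], self._P[6],
            self._P[7], self._P[8])
        tau = np.zeros(3)
        for i in range(6):
            tau[self.joint_of_muscle[i]] += f[i] * self.moment_arms[i]
        return tau

    def forces(self, q, qdot, activations):
        """Per-muscle total forces (N) at the given state."""
        return _core.muscle_forces(
            np.asarray(q, float), np.asarray(qdot, float),
            np.asarray(activations, float),
            self._P[2], self._P[3], self._P[4], self._P[5], self._P[6],
            self._P[7], self._P[8])

    # -- activation dynamics ----------------------------------------------

    def activation_step(self, chain: np.ndarray, u: float, dt: float):
        """Advance one muscle's third-order activation chain by dt (RK4).

        Returns (new_chain, a).  The chain is three cascaded first-order
        lags with time constant tau_activation; for constant u in [0, 1]
        the activation a converges monotonically to u and never leaves
        [0, 1].
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 <= u <= 1.0:
            raise ValueError("excitation u must be within [0, 1]")
        tau = self.config.muscles.tau_activation

        def deriv(c):
            return np.array([(u - c[0]), (c[0] - c[1]), (c[1] - c[2])]) / tau

        c = np.asarray(chain, float)
        k1 = deriv(c)
        k2 = deriv(c + 0.5 * dt * k1)
        k3 = deriv(c + 0.5 * dt * k2)
        k4 = deriv(c + dt * k3)
        c_new = c + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        return c_new, float(c_new[2])

    # -- scenario-level quantities ----------------------------------------

    def max_normalized_length(self, n_grid: int = 200) -> float:
        """Global max of lbar over a dense grid of feasible configurations.

        With constant moment arms each muscle's length depends on one joint
        only, so the maximum over the joint box is attained on a per-joint
        sweep; the dense grid is swept anyway as the generic check.
        """
        lo = np.asarray(self.config.geometry.joint_limits_lower, float)
        hi = np.asarray(self.config.geometry.joint_limits_upper, float)
        best = 0.0
        for j in range(3):
            qs = np.linspace(lo[j], hi[j], n_grid)
            for i in np.where(self.joint_of_muscle == j)[0]:
                rho = self.moment_arms[i] / self.l_0[i]
                lbar = 1.0 - rho * (qs - self.q_init[j])
                best = max(best, float(lbar.max()))
        return best


def severity_order(l_bar_max: float) -> list[str]:
    """Scenario labels A-H sorted by elongation work at l_bar_max."""
    from .config import SCENARIO_ORDER
    works = {
        lab: elongation_work(PassiveForceParams.from_scenario(lab), l_bar_max)
        for lab in SCENARIO_ORDER
    }
    return sorted(works, key=works.get)
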