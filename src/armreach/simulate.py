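"""Closed-loop reach simulation and target-set batch runs.

One reach: the arm starts at the initial posture at rest, tracks the
minimum-jerk plan to the target under the predictive PD +
inverse-dynamics controller, and continues through a homing window after
the plan ends.  The simulation is fully deterministic: no random numbers
appear anywhere in this module (randomness is confined to tuning).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _core, metrics
from .arm import Arm
from .config import ModelConfig, default_config
from .control import ControlParams, joint_reference
from .muscle import Muscles
from .plan import plan_reach, reach_duration
from .workspace import TargetSet


@dataclass
class ReachResult:
    """Time series and derived metrics for one simulated reach."""

    target: np.ndarray
    times: np.ndarray
    q: np.ndarray
    qdot: np.ndarray
    endpoint: np.ndarray
    activations: np.ndarray    # (n, 6)
    excitations: np.ndarray    # (n, 6)
    l_bar: np.ndarray          # (n, 6)
    f_tot: np.ndarray          # (n, 6)
    reference: np.ndarray      # planned endpoint path (n, 2)
    t_plan_end: float
    stable: bool
    e_h: float = np.nan        # mm
    e_mv: float = np.nan       # mm
    co_activation: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))
    failure_class: str = ""
    provenance: dict = field(default_factory=dict)

    def muscle_series(self) -> pd.DataFrame:
        """Per-muscle time series (t, l_bar, a, f_tot) in long format."""
        frames = []
        for i, name in enumerate(Muscles.NAMES):
            frames.append(pd.DataFrame({
                "t": self.times, "muscle": name, "l_bar": self.l_bar[:, i],
                "a": self.activations[:, i], "f_tot": self.f_tot[:, i],
            }))
        return pd.concat(frames, ignore_index=True)


class Simulator:
    """Reach simulator bound to one configuration and one scenario."""

    def __init__(self, config: ModelConfig | None = None,
                 scenario: str = "no_passive"):
        self.config = config or default_config()
        self.scenario = scenario
        self.arm = Arm(self.config)
        self.muscles = Muscles(self.config, scenario)
        self._P = self.muscles._P
        cc = self.config.control
        self.dt = 1.0 / cc.rate
        self.n_sub = cc.n_substeps

    def initial_state(self) -> np.ndarray:
        x0 = np.zeros(_core.NSTATE)
        x0[0:3] = self.arm.q_init
        return x0

    def simulate_reach(self, cp: ControlParams, target,
                       T: float | None = None) -> ReachResult:
        """Simulate one reach from the reset initial posture."""
        cc = self.config.control
        target = np.asarray(target, dtype=np.float64)
        start = self.arm.forward_kinematics(self.arm.q_init)
        if T is None:
            T = reach_duration(float(np.linalg.norm(target - start)),
                               cc.avg_speed, cc.t_min)
        plan = plan_reach(start, target, T, horizon=T + cc.homing_window,
                          dt=self.dt)
        qr, qdr, qddr = joint_reference(self.arm, plan, self.dt,
                                        cc.ik_feedback, cc.ik_damping,
                                        cc.ik_null_gain)
        Q, QD, EP, ACT, EXC, LBAR, FTOT, ok = _core.reach(
            self.initial_state(), qr, qdr, qddr,
            cp.kp, cp.kd, cp.n_pred, self.dt, self.n_sub, self._P)
        res = ReachResult(
            target=target, times=plan.times, q=Q, qdot=QD, endpoint=EP,
            activations=ACT, excitations=EXC, l_bar=LBAR, f_tot=FTOT,
            reference=plan.position, t_plan_end=plan.duration, stable=bool(ok),
            provenance={
                "scenario": self.scenario, "control": cp.provenance,
                "dt": self.dt, "n_substeps": self.n_sub,
                "homing_window": cc.homing_window, "T": float(T),
            })
        res.e_h = metrics.homing_in_error(res.times, res.endpoint, target,
                                          res.t_plan_end)
        res.e_mv = metrics.movement_error(res.times, res.endpoint,
                                          res.reference, res.t_plan_end)
        res.co_activation = np.array([
            metrics.co_activation(res.times, ACT[:, 2 * j], ACT[:, 2 * j + 1])
            for j in range(3)])
        res.failure_class = metrics.classify_failure(
            res.times, res.endpoint, target, res.t_plan_end, res.e_h)
        if not ok:
            res.failure_class = "oscillatory"  # violent integrator blow-up
        return res

    def run_target_set(self, cp: ControlParams, targets: TargetSet,
                       keep_series: bool = False):
        """Simulate every target in a set, each from reset.

        Returns (results, summary).  ``results`` is None unless
        ``keep_series``; the summary has one row per target, keyed by
        target index, with out-of-workspace targets flagged (they are kept
        in map exports but should be excluded from aggregate statistics).
        """
        rows = []
        results = [] if keep_series else None
        for k, point in enumerate(targets.points):
            res = self.simulate_reach(cp, point)
            rows.append({
                "target_id": k, "x": point[0], "y": point[1],
                "set_id": targets.set_id,
                "in_workspace": bool(targets.in_workspace[k]),
                "boundary_side": targets.boundary_side[k],
                "scenario": self.scenario,
                "e_h": res.e_h, "e_mv": res.e_mv,
                "coact_shoulder": res.co_activation[0],
                "coact_elbow": res.co_activation[1],
                "coact_wrist": res.co_activation[2],
                "failure_class": res.failure_class,
                "stable": res.stable,
            })
            if keep_series:
                results.append(res)
        return results, pd.DataFrame(rows)
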