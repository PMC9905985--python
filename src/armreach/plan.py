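"""Straight-path minimum-jerk reach planning.

The endpoint reference runs along the straight segment from start to
target with the classic minimum-jerk profile s(tau) = 10 tau^3 - 15 tau^4
+ 6 tau^5 (tau = t/T), giving a bell-shaped speed curve that is zero at
both ends with peak speed 1.875 d / T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def minimum_jerk(tau):
    """Normalized position s(tau) along the path, tau in [0, 1] (clipped)."""
    t = np.clip(np.asarray(tau, dtype=np.float64), 0.0, 1.0)
    return 10 * t**3 - 15 * t**4 + 6 * t**5


def minimum_jerk_rate(tau):
    """ds/dtau."""
    t = np.clip(np.asarray(tau, dtype=np.float64), 0.0, 1.0)
    return 30 * t**2 - 60 * t**3 + 30 * t**4


def minimum_jerk_accel(tau):
    """d2s/dtau2."""
    t = np.clip(np.asarray(tau, dtype=np.float64), 0.0, 1.0)
    return 60 * t - 180 * t**2 + 120 * t**3


@dataclass(frozen=True)
class ReachPlan:
    """A planned reach: straight path, minimum-jerk timing.

    ``times``/``position``/``velocity``/``acceleration`` sample the
    endpoint reference at the control rate over the full simulation
    horizon (plan duration T plus the homing window, during which the
    reference holds at the target with zero velocity).
    """

    start: np.ndarray
    target: np.ndarray
    duration: float
    horizon: float
    times: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray

    @property
    def distance(self) -> float:
        return float(np.linalg.norm(self.target - self.start))


def plan_reach(start, target, T: float, horizon: float | None = None,
               dt: float = 1e-3) -> ReachPlan:
    """Plan a reach of duration T sampled every dt up to ``horizon``.

    start == target is allowed (degenerate plan: hold position).  Targets
    outside the workspace are planned like any other; no clamping.
    """
    if T <= 0:
        raise ValueError("duration T must be positive")
    start = np.asarray(start, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if horizon is None:
        horizon = T
    n = int(round(horizon / dt)) + 1
    t = np.arange(n) * dt
    tau = t / T
    s = minimum_jerk(tau)
    sd = np.where(tau <= 1.0, minimum_jerk_rate(tau) / T, 0.0)
    sdd = np.where(tau <= 1.0, minimum_jerk_accel(tau) / T**2, 0.0)
    d = target - start
    pos = start[None, :] + s[:, None] * d[None, :]
    vel = sd[:, None] * d[None, :]
    acc = sdd[:, None] * d[None, :]
    return ReachPlan(start=start, target=target, duration=float(T),
                     horizon=float(horizon), times=t, position=pos,
                     velocity=vel, acceleration=acc)


def reach_duration(distance: float, avg_speed: float, t_min: float) -> float:
    """Reach duration rule: T = max(t_min, d / avg_speed)."""
    return max(t_min, distance / avg_speed)
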