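"""Model configuration: validated parameter blocks and YAML round-tripping.

All physical, muscle, controller, integrator and study settings live in one
versioned configuration object.  Nothing numeric is hard-coded in the
dynamics kernels; they receive packed arrays produced by
:meth:`ModelConfig.pack`.

Units are SI throughout: metres, kilograms, seconds, radians, newtons.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

CONFIG_VERSION = 1

#: Passive-curve parameter triples (s_p, r_p, l_p) for the nine study
#: scenarios: a no-passive-force reference plus ageing scenarios A-H in
#: order of increasing severity (by the work to elongate a muscle to its
#: maximum length in the model).
SCENARIOS: dict[str, tuple[float, float, float]] = {
    "no_passive": (0.05, 5.0, 1.3),
    "A": (0.05, 5.0, 1.1),
    "B": (0.075, 5.0, 1.1),
    "C": (0.05, 8.0, 1.1),
    "D": (0.075, 8.0, 1.1),
    "E": (0.05, 5.0, 1.0),
    "F": (0.075, 5.0, 1.0),
    "G": (0.05, 8.0, 1.0),
    "H": (0.075, 8.0, 1.0),
}

SCENARIO_ORDER = ["A", "B", "C", "D", "E", "F", "G", "H"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class GeometryConfig(_Block):
    """Rigid-body geometry of the planar arm (upper arm, forearm, hand).

    The shoulder sits at the origin; the chest bar runs along the negative
    x axis over ``chest_span`` metres.  Angles are measured counter-
    clockwise, flexion positive.
    """

    segment_lengths: list[float] = [0.31, 0.27, 0.15]
    segment_masses: list[float] = [2.1, 1.2, 0.5]
    segment_inertias: list[float] = [0.0182, 0.0079, 0.0010]
    segment_com_offsets: list[float] = [0.1395, 0.1161, 0.060]
    joint_limits_lower: list[float] = [0.0, 0.0, -0.7]
    joint_limits_upper: list[float] = [math.pi, 2.618, 0.7]
    initial_joint_angles: list[float] = [math.pi / 3.0, math.pi / 2.0, 0.0]
    chest_span: float = 0.44
    limit_stiffness: float = 200.0  # N m / rad, one-sided penalty
    limit_damping: float = 5.0      # N m s / rad, engaged beyond a limit

    @model_validator(mode="after")
    def _check(self):
        for key in ("segment_lengths", "segment_masses", "segment_inertias",
                    "segment_com_offsets"):
            vals = getattr(self, key)
            if len(vals) != 3:
                raise ValueError(f"geometry.{key}: expected 3 entries")
            if any(v <= 0 for v in vals):
                raise ValueError(f"geometry.{key}: entries must be positive")
        for c, l in zip(self.segment_com_offsets, self.segment_lengths):
            if c > l:
                raise ValueError("geometry.segment_com_offsets: COM beyond segment tip")
        for j, (lo, hi) in enumerate(zip(self.joint_limits_lower, self.joint_limits_upper)):
            if not lo < hi:
                raise ValueError(f"geometry.joint_limits[{j}]: min must be < max")
            if not lo <= self.initial_joint_angles[j] <= hi:
                raise ValueError(f"geometry.initial_joint_angles[{j}]: outside joint limits")
        if self.chest_span <= 0 or self.limit_stiffness <= 0 or self.limit_damping < 0:
            raise ValueError("geometry: chest_span/limit_stiffness must be positive")
        return self


class MuscleConfig(_Block):
    """Six Hill-type muscles: one flexor/extensor pair per joint.

    Muscle paths are straight-line equivalents with constant moment arms:
    ``l(q) = l0 - r (q_j - q_init_j)`` with signed moment arm r (flexor
    positive).  At the initial posture every muscle sits exactly at its
    optimal length (l/l0 = 1), so a slack length l_p = 1 makes any movement
    away from the initial angles evoke passive force at the moving joint.
    Moment arms are sized so the largest normalized elongation over the
    feasible joint box stays below 1.26.
    """

    f_max: list[float] = [1200.0, 1200.0, 800.0, 800.0, 400.0, 400.0]
    l_0: list[float] = [0.15, 0.15, 0.12, 0.12, 0.08, 0.08]
    moment_arm: list[float] = [0.01725, -0.01725, 0.0144, -0.0144, 0.016, -0.016]
    joint_of_muscle: list[int] = [0, 0, 1, 1, 2, 2]
    tau_activation: float = 0.015  # s, each stage of the third-order chain
    v_max: float = 10.0            # optimal lengths per second
    gamma_fl: float = 0.45         # width of the Gaussian force-length curve
    ecc_gain: float = 0.5          # eccentric force plateau above isometric
    ecc_shape: float = 0.05        # eccentric curvature (normalized velocity)
    conc_shape: float = 0.25       # Hill concentric curvature constant
    fa_floor: float = 0.05         # lower clamp on f_a in the excitation inversion

    @model_validator(mode="after")
    def _check(self):
        for key in ("f_max", "l_0", "moment_arm", "joint_of_muscle"):
            if len(getattr(self, key)) != 6:
                raise ValueError(f"muscles.{key}: expected 6 entries")
        if any(v <= 0 for v in self.f_max) or any(v <= 0 for v in self.l_0):
            raise ValueError("muscles.f_max/l_0: entries must be positive")
        for j in range(3):
            rf, re = self.moment_arm[2 * j], self.moment_arm[2 * j + 1]
            if not (rf > 0 > re):
                raise ValueError(f"muscles.moment_arm: pair at joint {j} must be (+, -)")
            if self.joint_of_muscle[2 * j] != j or self.joint_of_muscle[2 * j + 1] != j:
                raise ValueError("muscles.joint_of_muscle: expected [0,0,1,1,2,2]")
        for key in ("tau_activation", "v_max", "gamma_fl", "ecc_shape", "conc_shape", "fa_floor"):
            if getattr(self, key) <= 0:
                raise ValueError(f"muscles.{key}: must be positive")
        return self


class ControlConfig(_Block):
    """Controller/plan timing (the seven tuned gains live in ControlParams)."""

    rate: float = 1000.0        # Hz, zero-order-hold control rate
    n_substeps: int = 4         # RK4 substeps per control period
    homing_window: float = 1.0  # s simulated beyond the end of the plan
    avg_speed: float = 0.5      # m/s, sets reach duration T = max(T_min, d/avg_speed)
    t_min: float = 0.6          # s, floor on reach duration
    ik_feedback: float = 50.0   # 1/s, endpoint feedback in the reference IK
    ik_damping: float = 0.01    # m, damped-least-squares regularization
    ik_null_gain: float = 5.0   # 1/s, nullspace pull toward the goal configuration

    @model_validator(mode="after")
    def _check(self):
        if self.ik_null_gain < 0:
            raise ValueError("control.ik_null_gain: must be >= 0")
        for key in ("rate", "homing_window", "avg_speed", "t_min", "ik_feedback", "ik_damping"):
            if getattr(self, key) <= 0:
                raise ValueError(f"control.{key}: must be positive")
        if self.n_substeps < 1:
            raise ValueError("control.n_substeps: must be >= 1")
        return self


class GAConfig(_Block):
    """Desk-scale defaults for the mixed-integer genetic algorithm."""

    population: int = 40
    generations: int = 60
    elites: int = 2
    tournament: int = 3
    crossover_prob: float = 0.7
    mutation_prob: float = 0.2
    mutation_sigma: float = 0.1      # fraction of each gene's range
    kp_max: float = 1000.0           # N m / rad
    kd_max: float = 50.0             # N m s / rad
    n_pred_max: int = 25             # control steps

    @model_validator(mode="after")
    def _check(self):
        if self.population < 2 or self.generations < 1:
            raise ValueError("ga.population/generations: too small")
        if self.elites >= self.population:
            raise ValueError("ga.elites: must be < population")
        if self.kp_max <= 0 or self.kd_max <= 0 or self.n_pred_max < 0:
            raise ValueError("ga.kp_max/kd_max/n_pred_max: invalid bounds")
        return self


class TargetConfig(_Block):
    """Target-set construction parameters (see workspace module)."""

    grid_spacing: float = 0.05        # m, rectangular grid (set ii)
    band_width: float = 0.20          # m, boundary band depth (set iii)
    n_rings: int = 5                  # concentric rings in set (iii)
    arc_step: float = 0.131           # rad, angular spacing along boundary arcs
    opt_targets: list[list[float]] = [
        [-0.55, 0.28],   # distal left
        [0.606, 0.35],   # distal right
        [0.30, 0.45],    # proximal right
        [0.0, 0.70],     # distal forward
    ]

    @model_validator(mode="after")
    def _check(self):
        if self.grid_spacing <= 0 or self.band_width <= 0 or self.arc_step <= 0:
            raise ValueError("targets.grid_spacing/band_width/arc_step: must be positive")
        if self.n_rings < 2:
            raise ValueError("targets.n_rings: must be >= 2")
        if len(self.opt_targets) != 4:
            raise ValueError("targets.opt_targets: exactly 4 targets required")
        return self


class ModelConfig(_Block):
    """Full model configuration (versioned)."""

    version: int = CONFIG_VERSION
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    muscles: MuscleConfig = Field(default_factory=MuscleConfig)
    control: ControlConfig = Field(default_factory=ControlConfig)
    ga: GAConfig = Field(default_factory=GAConfig)
    targets: TargetConfig = Field(default_factory=TargetConfig)

    def pack(self, scenario: str | tuple[float, float, float] = "no_passive"):
        """Pack parameters into the array tuple the compiled kernels expect."""
        g, m = self.geometry, self.muscles
        arm = np.array([
            g.segment_lengths, g.segment_masses, g.segment_inertias,
            g.segment_com_offsets, g.joint_limits_lower, g.joint_limits_upper,
        ], dtype=np.float64)
        L = arm[0]
        mass = arm[1]
        c = arm[3]
        beta = np.zeros((3, 3))
        for k in range(3):
            for j in range(3):
                if j < k:
                    beta[k, j] = L[j]
                elif j == k:
                    beta[k, j] = c[k]
        A = np.einsum("k,kj,kl->jl", mass, beta, beta)
        if isinstance(scenario, str):
            sp, rp, lp = SCENARIOS[scenario]
        else:
            sp, rp, lp = scenario
        misc = np.array([
            g.limit_stiffness, g.limit_damping, m.tau_activation, m.v_max,
            m.gamma_fl, m.ecc_gain, m.ecc_shape, m.conc_shape, m.fa_floor,
        ], dtype=np.float64)
        return (
            arm,
            A,
            np.asarray(m.f_max, dtype=np.float64),
            np.asarray(m.l_0, dtype=np.float64),
            np.asarray(m.moment_arm, dtype=np.float64),
            np.asarray(g.initial_joint_angles, dtype=np.float64),
            np.asarray(m.joint_of_muscle, dtype=np.int64),
            np.array([sp, rp, lp], dtype=np.float64),
            misc,
        )


def default_config() -> ModelConfig:
    """The package's versioned default configuration."""
    return ModelConfig()


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load and validate a YAML configuration file (defaults if path is None).

    Unknown keys and out-of-range values raise with the offending key named.
    """
    if path is None:
        return default_config()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ModelConfig.model_validate(raw)


def dump_config(cfg: ModelConfig, path: str | Path) -> None:
    """Write a configuration as YAML (round-trips through load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)
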