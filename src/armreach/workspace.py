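"""Workspace-boundary estimation and target-set generation.

The geometrical workspace is the set of endpoint positions reachable over
the feasible joint box.  Its boundary is estimated from the forward-
kinematic images of the box's faces (a boundary point must have some joint
at a limit or a singular Jacobian, and for this arm the singular set lies
on the faces' images' envelope), outlined with a concave hull so that
every polygon vertex is itself the image of a feasible configuration.

Three target sets are generated:

(i)   ``opt_sequence`` — four targets near the edges of the workspace,
      used for control-parameter optimization;
(ii)  ``rect_grid`` — a rectangular grid over the workspace bounding box;
(iii) ``boundary_grid`` — concentric rings covering the distal boundary
      and a band inside it, split into right (straight arm over the full
      shoulder range) and left (straight forearm+hand over the full elbow
      range at full shoulder flexion) subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

from .arm import Arm


@dataclass
class TargetSet:
    """Labelled planar targets with workspace annotations."""

    set_id: str  # one of {opt_sequence, rect_grid, boundary_grid}
    points: np.ndarray              # (n, 2) metres
    in_workspace: np.ndarray        # (n,) bool
    boundary_side: list[str]        # per point: "right", "left" or "none"

    def __post_init__(self):
        if len(self.points) == 0:
            raise ValueError(f"target set {self.set_id!r} is empty")
        if self.set_id == "opt_sequence" and len(self.points) != 4:
            raise ValueError("opt_sequence must have exactly 4 targets")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.points[:, 0], "y": self.points[:, 1],
            "set_id": self.set_id, "in_workspace": self.in_workspace,
            "boundary_side": self.boundary_side,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TargetSet":
        return cls(set_id=str(df["set_id"].iloc[0]),
                   points=df[["x", "y"]].to_numpy(float),
                   in_workspace=df["in_workspace"].to_numpy(bool),
                   boundary_side=list(df["boundary_side"]))


def _face_samples(arm: Arm, n: int) -> np.ndarray:
    """Endpoint images of the six faces of the feasible joint box."""
    lo, hi = arm.joint_limits_lower, arm.joint_limits_upper
    grids = [np.linspace(lo[j], hi[j], n) for j in range(3)]
    pts = []
    for j_fixed in range(3):
        others = [j for j in range(3) if j != j_fixed]
        a, b = np.meshgrid(grids[others[0]], grids[others[1]], indexing="ij")
        for val in (lo[j_fixed], hi[j_fixed]):
            q = np.zeros((a.size, 3))
            q[:, j_fixed] = val
            q[:, others[0]] = a.ravel()
            q[:, others[1]] = b.ravel()
            pts.append(q)
    qs = np.vstack(pts)
    th1 = qs[:, 0]
    th2 = th1 + qs[:, 1]
    th3 = th2 + qs[:, 2]
    L = arm.L
    x = L[0] * np.cos(th1) + L[1] * np.cos(th2) + L[2] * np.cos(th3)
    y = L[0] * np.sin(th1) + L[1] * np.sin(th2) + L[2] * np.sin(th3)
    return np.column_stack([x, y])


def estimate_workspace(arm: Arm, resolution: int = 80,
                       hull_ratio: float = 0.03) -> Polygon:
    """Estimated workspace boundary polygon.

    ``resolution`` is the per-axis sample count on each face of the joint
    box; the outline is the shapely concave hull of the sampled endpoint
    images, so every vertex is the forward-kinematics image of a feasible
    configuration.  Deterministic for fixed resolution.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    pts = _face_samples(arm, resolution)
    hull = shapely.concave_hull(shapely.MultiPoint(pts), ratio=hull_ratio)
    if not isinstance(hull, Polygon):  # pragma: no cover
        hull = hull.convex_hull
    return hull


def in_workspace(point, boundary: Polygon, tol: float = 1e-9) -> bool:
    """Point-in-polygon test; boundary points count as inside."""
    return bool(boundary.covers(Point(point)) or
                boundary.exterior.distance(Point(point)) <= tol)


def _right_boundary_point(arm: Arm, theta: float, offset: float) -> np.ndarray:
    """Point on/inside the right boundary: straight arm at shoulder angle
    theta, pulled radially inward by ``offset`` metres."""
    r = arm.reach_length - offset
    return r * np.array([np.cos(theta), np.sin(theta)])

def _left_boundary_point(arm: Arm, phi: float, offset: float) -> np.ndarray:
    """Point on/inside the left boundary: shoulder fully flexed, straight
    forearm+hand at elbow angle phi, pulled toward the elbow by ``offset``."""
    q1 = arm.joint_limits_upper[0]
    centre = arm.L[0] * np.array([np.cos(q1), np.sin(q1)])
    r = arm.L[1] + arm.L[2] - offset
    ang = q1 + phi
    return centre + r * np.array([np.cos(ang), np.sin(ang)])


def make_target_sets(arm: Arm, boundary: Polygon,
                     config=None) -> dict[str, TargetSet]:
    """Generate the three study target sets (see module docstring)."""
    cfg = (config or arm.config).targets
    sets: dict[str, TargetSet] = {}

    # (i) optimization sequence
    pts = np.asarray(cfg.opt_targets, dtype=np.float64)
    sets["opt_sequence"] = TargetSet(
        "opt_sequence", pts,
        np.array([in_workspace(p, boundary) for p in pts]),
        ["none"] * len(pts))

    # (ii) rectangular grid over the workspace bounding box
    minx, miny, maxx, maxy = boundary.bounds
    h = cfg.grid_spacing
    xs = np.arange(np.floor(minx / h) * h, maxx + h / 2, h)
    ys = np.arange(np.floor(miny / h) * h, maxy + h / 2, h)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    sets["rect_grid"] = TargetSet(
        "rect_grid", grid,
        np.array([in_workspace(p, boundary) for p in grid]),
        ["none"] * len(grid))

    # (iii) concentric boundary rings: right and left subsets
    offsets = np.linspace(0.0, cfg.band_width, cfg.n_rings)
    pts3, side3 = [], []
    lo, hi = arm.joint_limits_lower, arm.joint_limits_upper
    for off in offsets:
        n_r = max(2, int(np.ceil((hi[0] - lo[0]) / cfg.arc_step)) + 1)
        for th in np.linspace(lo[0], hi[0], n_r):
            pts3.append(_right_boundary_point(arm, th, off))
            side3.append("right")
        n_l = max(2, int(np.ceil((hi[1] - lo[1]) / cfg.arc_step)) + 1)
        for ph in np.linspace(lo[1], hi[1], n_l):
            pts3.append(_left_boundary_point(arm, ph, off))
            side3.append("left")
    pts3 = np.asarray(pts3)
    sets["boundary_grid"] = TargetSet(
        "boundary_grid", pts3,
        np.array([in_workspace(p, boundary) for p in pts3]),
        side3)
    return sets
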