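"""Reach performance metrics and failure classification.

Two errors characterize each reach.  The homing-in error e_h is the
time-averaged endpoint-to-target distance over the homing phase (from the
time the planned trajectory reaches the target to the end of the
simulation); it measures final accuracy and doubles as a dynamic-stability
indicator.  The movement error e_mv is the time-averaged deviation of the
endpoint from the planned reference over the reach itself (tracking
accuracy).  Per-joint co-activation is the time average of the smaller of
the two antagonists' activations over the whole movement.  All averages
use trapezoidal integration so they are robust to the sampling step.

Failed reaches fall into two classes: stopping short (the arm decelerates
and stabilizes before the target; a static force balance) and oscillatory
(the arm fails to stabilize, oscillating chaotically or with quasi-steady
amplitude).  The detector counts sign changes of the slope of the
distance-to-target signal during the homing phase, with an amplitude
floor, both configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SUCCESS_THRESHOLD_MM = 1.0     # taxonomy success cut (coarse reporting level)
OSC_SIGN_CHANGES = 6           # slope sign changes for the oscillation label
OSC_AMPLITUDE_MM = 1.0         # amplitude floor for the oscillation label

FAILURE_CLASSES = ("success", "stopping_short", "oscillatory")


def _trapz_mean(y: np.ndarray, t: np.ndarray) -> float:
    if len(y) < 2:
        return float(y[0]) if len(y) else 0.0
    return float(np.trapezoid(y, t) / (t[-1] - t[0]))


def homing_in_error(times, endpoint, target, t_plan_end) -> float:
    """Time-averaged endpoint-to-target distance (mm) over the homing phase."""
    times = np.asarray(times, float)
    mask = times >= t_plan_end - 1e-12
    if not mask.any():
        raise ValueError("homing phase is empty")
    d = np.linalg.norm(np.asarray(endpoint, float)[mask] - np.asarray(target, float), axis=1)
    return 1e3 * _trapz_mean(d, times[mask])


def movement_error(times, endpoint, reference, t_plan_end) -> float:
    """Time-averaged deviation (mm) from the planned path over [0, T]."""
    times = np.asarray(times, float)
    mask = times <= t_plan_end + 1e-12
    if not mask.any():
        raise ValueError("plan phase is empty")
    d = np.linalg.norm(np.asarray(endpoint, float)[mask] - np.asarray(reference, float)[mask], axis=1)
    return 1e3 * _trapz_mean(d, times[mask])


def co_activation(times, a_flexor, a_extensor) -> float:
    """Time average of min(a_flexor, a_extensor) over the whole movement."""
    m = np.minimum(np.asarray(a_flexor, float), np.asarray(a_extensor, float))
    return _trapz_mean(m, np.asarray(times, float))


@dataclass(frozen=True)
class FailureThresholds:
    success_mm: float = SUCCESS_THRESHOLD_MM
    osc_sign_changes: int = OSC_SIGN_CHANGES
    osc_amplitude_mm: float = OSC_AMPLITUDE_MM


def classify_failure(times, endpoint, target, t_plan_end, e_h_mm: float,
                     thresholds: FailureThresholds | None = None) -> str:
    """Label one reach as success, stopping_short or oscillatory."""
    th = thresholds or FailureThresholds()
    if e_h_mm <= th.success_mm:
        return "success"
    times = np.asarray(times, float)
    mask = times >= t_plan_end - 1e-12
    d = np.linalg.norm(np.asarray(endpoint, float)[mask] - np.asarray(target, float), axis=1)
    dd = np.diff(d)
    dd = dd[np.abs(dd) > 0]
    n_changes = int(np.sum(np.signbit(dd[1:]) != np.signbit(dd[:-1])))
    amplitude_mm = 1e3 * (d.max() - d.min())
    if n_changes > th.osc_sign_changes and amplitude_mm > th.osc_amplitude_mm:
        return "oscillatory"
    return "stopping_short"


def failure_fraction(e_h_values, in_workspace, threshold_mm: float,
                     side=None, boundary_side=None) -> float:
    """Fraction of in-workspace targets with e_h above threshold_mm.

    If ``side`` is given, restrict to targets whose ``boundary_side``
    annotation matches.
    """
    e = np.asarray(e_h_values, float)
    keep = np.asarray(in_workspace, bool).copy()
    if side is not None:
        keep &= np.asarray(boundary_side) == side
    if not keep.any():
        raise ValueError("no in-workspace targets in the requested subset")
    return float(np.mean(e[keep] > threshold_mm))
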