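"""Passive hip-coupling spring model.

A single torsional element couples the two hips and applies a torque
proportional to the instantaneous difference between left and right hip
angles, ``tau_a = alpha * K_inv * dtheta`` with ``dtheta = q_hip_left -
q_hip_right``.  ``K_inv`` is the stiffness that minimises the
stride-integral of the squared residual (biological) hip moment — a scalar
least-squares problem with a closed form — and the dimensionless spring
coefficient ``alpha`` scales it: ``alpha = 0`` is no assistance, ``alpha =
1`` full least-squares hip-moment compensation.

Action-reaction is built in: one hip receives ``+tau_a``, the other
``-tau_a``, so the applied torques sum to zero at every sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gait_synth import GaitTrial

__all__ = [
    "DegenerateCalibrationError",
    "ExoCalibration",
    "HipTorqueDecomposition",
    "stride_integral",
    "delta_theta",
    "calibrate_kinv",
    "calibrate_trial",
    "assistive_torque",
    "residual_hip_moment",
    "squared_moment_integral",
    "alpha_optimum_for_squared_moment",
]

#: deflection beyond which a physical leaf spring would leave its linear range
LINEAR_RANGE_RAD = np.deg2rad(30.0)


class DegenerateCalibrationError(ValueError):
    """The hip-angle difference is identically zero: no spring can act."""


@dataclass(frozen=True)
class ExoCalibration:
    """Calibrated spring: stiffness ``k_inv`` (N*m/rad), coefficient ``alpha``.

    ``assist_side`` names the hip that receives ``+alpha*k_inv*dtheta``; the
    contralateral hip receives the reaction torque.
    """

    k_inv: float
    alpha: float = 0.0
    assist_side: str = "right"

    def __post_init__(self):
        if not np.isfinite(self.k_inv):
            raise ValueError("k_inv must be finite")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.assist_side not in ("left", "right"):
            raise ValueError(f"assist_side must be 'left' or 'right', got {self.assist_side!r}")

    def with_alpha(self, alpha: float) -> "ExoCalibration":
        return ExoCalibration(self.k_inv, alpha, self.assist_side)


@dataclass
class HipTorqueDecomposition:
    """Per-sample split of the hip moment under exoskeleton assistance.

    ``tau_bio[side] = baseline[side] - applied[side]`` everywhere;
    ``region`` labels each sample ``improve`` (amplitude reduced, sign
    kept), ``disrupt`` (amplitude increased or sign flipped) or ``neutral``
    (no assistance, or baseline below the sign tolerance).
    """

    dtheta: np.ndarray
    applied: dict
    tau_bio: dict
    baseline: dict
    region: dict
    calibration: ExoCalibration


def stride_integral(y: np.ndarray, time: np.ndarray, period: float) -> float:
    """Trapezoidal integral of a periodic series over one full stride.

    The sample grid excludes the endpoint ``T``; the closing segment from
    the last sample back to ``y(0)`` (= ``y(T)`` by periodicity) is included
    so harmonic orthogonality holds exactly on uniform grids.
    """
    y = np.asarray(y, dtype=float)
    inner = np.trapezoid(y, time)
    dt_wrap = period - time[-1] + time[0]
    return float(inner + 0.5 * (y[-1] + y[0]) * dt_wrap)


def delta_theta(trial: GaitTrial) -> np.ndarray:
    """Hip-angle difference ``q_hip_left - q_hip_right`` on the trial grid."""
    return trial.angles[("hip", "left")] - trial.angles[("hip", "right")]


def calibrate_kinv(
    tau_hip: dict,
    dtheta: np.ndarray,
    time: np.ndarray,
    period: float,
    assist_side: str = "right",
) -> float:
    """Least-squares spring stiffness over one stride, both hips jointly.

    Minimises ``J(K) = int (tau_r - s_r K dtheta)^2 + (tau_l - s_l K
    dtheta)^2 dt`` where ``s`` is +1 on the assisted side and -1 on the
    other; the closed form is the ratio of the cross-moment integral to
    twice the squared-dtheta integral.  Raises
    :class:`DegenerateCalibrationError` when ``dtheta`` is identically zero
    (the objective is flat and the spring cannot act).
    """
    dtheta = np.asarray(dtheta, dtype=float)
    if tau_hip["left"].shape != dtheta.shape or tau_hip["right"].shape != dtheta.shape:
        raise ValueError("torque and dtheta series must share the grid")
    denom = stride_integral(dtheta**2, time, period)
    if denom <= 0.0 or not np.any(dtheta != 0.0):
        raise DegenerateCalibrationError("dtheta is identically zero over the stride")
    sign = 1.0 if assist_side == "right" else -1.0
    cross = stride_integral((tau_hip["right"] - tau_hip["left"]) * dtheta, time, period)
    return float(sign * cross / (2.0 * denom))


def calibrate_trial(trial: GaitTrial, assist_side: str = "right") -> ExoCalibration:
    """Calibrate ``K_inv`` on a trial's baseline hip moments."""
    dth = delta_theta(trial)
    tau = {s: trial.moments[("hip", s)] for s in ("left", "right")}
    k = calibrate_kinv(tau, dth, trial.time, trial.stride_period, assist_side)
    return ExoCalibration(k_inv=k, alpha=0.0, assist_side=assist_side)


def assistive_torque(calib: ExoCalibration, dtheta: np.ndarray, warn_linear_range: bool = False) -> dict:
    """Per-side exoskeleton torque ``+/- alpha * K_inv * dtheta``.

    With ``warn_linear_range`` a :class:`UserWarning` is emitted when the
    peak deflection exceeds the 30 degree linear range of a physical leaf
    spring; the returned torque stays linear regardless.
    """
    dtheta = np.asarray(dtheta, dtype=float)
    if warn_linear_range and np.max(np.abs(dtheta)) > LINEAR_RANGE_RAD:
        import warnings

        warnings.warn(
            "peak |dtheta| exceeds the 30 deg linear spring range; "
            "the linear torque model is extrapolating",
            UserWarning,
            stacklevel=2,
        )
    tau = calib.alpha * calib.k_inv * dtheta
    other = "left" if calib.assist_side == "right" else "right"
    return {calib.assist_side: tau, other: -tau}


def _classify(baseline: np.ndarray, tau_bio: np.ndarray, applied: np.ndarray, sign_tolerance: float) -> np.ndarray:
    labels = np.full(baseline.shape, "neutral", dtype="<U7")
    active = np.abs(applied) > 0.0
    sig = np.abs(baseline) >= sign_tolerance
    same_sign = np.sign(tau_bio) == np.sign(baseline)
    improve = active & sig & same_sign & (np.abs(tau_bio) < np.abs(baseline))
    disrupt = active & sig & (~same_sign | (np.abs(tau_bio) > np.abs(baseline)))
    labels[improve] = "improve"
    labels[disrupt] = "disrupt"
    return labels


def residual_hip_moment(
    trial: GaitTrial,
    calib: ExoCalibration,
    sign_tolerance: float = 0.5,
) -> HipTorqueDecomposition:
    """Residual biological hip moment after subtracting the spring torque.

    Knee and ankle baselines are untouched by the device (it spans the hips
    only).  ``sign_tolerance`` (N*m) is the baseline amplitude below which a
    sample is labelled ``neutral`` rather than improve/disrupt, avoiding
    label chatter near moment zero crossings.
    """
    dth = delta_theta(trial)
    applied = assistive_torque(calib, dth)
    baseline = {s: trial.moments[("hip", s)] for s in ("left", "right")}
    tau_bio = {s: baseline[s] - applied[s] for s in ("left", "right")}
    region = {s: _classify(baseline[s], tau_bio[s], applied[s], sign_tolerance) for s in ("left", "right")}
    return HipTorqueDecomposition(
        dtheta=dth,
        applied=applied,
        tau_bio=tau_bio,
        baseline=baseline,
        region=region,
        calibration=calib,
    )


def squared_moment_integral(trial: GaitTrial, calib: ExoCalibration, alpha: float) -> float:
    """``J(alpha)``: stride integral of the squared residual hip moment, both sides."""
    dec = residual_hip_moment(trial, calib.with_alpha(alpha))
    total = sum(
        stride_integral(dec.tau_bio[s] ** 2, trial.time, trial.stride_period)
        for s in ("left", "right")
    )
    return float(total)


def alpha_optimum_for_squared_moment(trial: GaitTrial, calib: ExoCalibration) -> float:
    """Continuous-alpha minimiser of the squared residual hip moment.

    ``J(alpha)`` is a convex quadratic whose minimiser is the ratio of the
    freshly calibrated stiffness to ``calib.k_inv``; when ``calib`` came
    from :func:`calibrate_trial` on the same trial this is exactly 1 — the
    least-squares projection cannot be improved by rescaling.

    A stiffness below 1e-9 N*m/rad — orders of magnitude under any
    physical spring — marks a degenerate calibration (hip moment
    numerically orthogonal to the hip-angle difference) and raises.
    """
    if abs(calib.k_inv) < 1e-9:
        raise DegenerateCalibrationError(
            "k_inv is (numerically) zero: hip moment orthogonal to dtheta"
        )
    fresh = calibrate_trial(trial, assist_side=calib.assist_side)
    return float(fresh.k_inv / calib.k_inv)
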