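"""Per-frame muscle-redundancy resolution by convex quadratic programming.

At each time frame the muscle forces ``f``, joint reserve torques ``r`` and
optional residual torques ``R`` minimise

    J(f, r, R) = sum_i (f_i / w_i)^2 + sum_j (r_j / w_j)^2 + sum_k (R_k / w_k)^2

subject to the joint-moment equalities ``A f + r (+ R) = tau_target`` per
joint and the bounds ``0 <= f_i <= f_iso_i``.  With the default weights
``w_i = f_iso_i`` the muscle term is the summed squared normalized force
(the classic effort/fatigue cost); reserve weights are small against the
moment scale, so reserves are expensive and act as feasibility slacks only.

The solver works on the dual: with a diagonal Hessian, stationarity gives
``f_i = clip(w_i^2 (A^T lam)_i / 2, 0, f_iso_i)`` and ``r_j = w_r^2 lam_j /
2`` for the joint multipliers ``lam``, so the dual equation ``g(lam) = A
f(lam) + D_r lam - tau = 0`` is piecewise linear and strictly monotone (the
free reserves guarantee a positive-definite Jacobian).  A semismooth Newton
iteration with backtracking solves it to machine-level KKT residuals in a
handful of steps; the solution of a convex QP with strictly convex
objective is unique, so repeated solves agree bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exo_spring import HipTorqueDecomposition
from .gait_synth import JOINTS, SIDES, GaitTrial
from .muscle_model import MuscleModelSpec, moment_arm_matrix

__all__ = [
    "SolverError",
    "FrameProblem",
    "FrameSolution",
    "MuscleSolution",
    "solve_frame",
    "solve_trial",
    "frame_problems",
]


class SolverError(RuntimeError):
    """The dual iteration failed to reach the requested KKT tolerance."""


@dataclass
class FrameProblem:
    """One frame of the redundancy QP.

    ``arm_matrix`` is joints x muscles; ``targets`` the joint moments the
    actuators must reproduce (N*m).  ``residual_weight`` enables per-joint
    residual slacks mirroring the structural role of model-ground
    residuals; ``None`` (default) disables them.
    """

    targets: np.ndarray
    arm_matrix: np.ndarray
    f_iso: np.ndarray
    muscle_weights: np.ndarray
    reserve_weight: float = 1.0
    residual_weight: float | None = None

    def validate(self) -> None:
        if not np.all(np.isfinite(self.arm_matrix)):
            raise ValueError("arm matrix must be finite")
        if not np.all(np.isfinite(self.targets)):
            raise ValueError("target moments must be finite")
        if np.any(self.muscle_weights <= 0) or self.reserve_weight <= 0:
            raise ValueError("weights must be strictly positive (convexity)")
        if self.residual_weight is not None and self.residual_weight <= 0:
            raise ValueError("residual weight must be strictly positive")
        if np.any(self.f_iso <= 0):
            raise ValueError("f_iso bounds must be positive")


@dataclass
class FrameSolution:
    forces: np.ndarray
    reserves: np.ndarray
    residuals: np.ndarray
    objective: float
    kkt_residual: float
    iterations: int
    multipliers: np.ndarray | None = None


def _objective(p: FrameProblem, f, r, R) -> float:
    val = np.sum((f / p.muscle_weights) ** 2) + np.sum((r / p.reserve_weight) ** 2)
    if p.residual_weight is not None:
        val += np.sum((R / p.residual_weight) ** 2)
    return float(val)


def solve_frame(
    problem: FrameProblem,
    tol: float = 1e-10,
    kkt_tol: float = 1e-8,
    max_iter: int = 200,
    lam0: np.ndarray | None = None,
) -> FrameSolution:
    """Solve one frame's QP to global optimality.

    ``tol`` is the dual-equation (= moment-constraint) tolerance relative
    to the target scale; ``kkt_tol`` the verified stationarity residual.
    ``lam0`` warm-starts the joint multipliers (used across consecutive
    frames of a trial, where targets move slowly).
    """
    problem.validate()
    A = problem.arm_matrix
    n_j = A.shape[0]
    b = np.asarray(problem.targets, dtype=float)
    wm2 = problem.muscle_weights**2 / 2.0
    dr = problem.reserve_weight**2 / 2.0
    dres = (problem.residual_weight**2 / 2.0) if problem.residual_weight is not None else 0.0
    diag = dr + dres  # free slacks: r_j = dr*lam_j, R_j = dres*lam_j

    inv_w2 = 1.0 / problem.muscle_weights**2

    def primal(lam):
        return np.clip(wm2 * (A.T @ lam), 0.0, problem.f_iso)

    def g(lam):
        return A @ primal(lam) + diag * lam - b

    def dual_value(lam):
        # q(lam) = min_x L(x, lam); concave, C^1, piecewise quadratic.
        u = A.T @ lam
        f = np.clip(wm2 * u, 0.0, problem.f_iso)
        return float(np.sum(inv_w2 * f**2 - u * f) + lam @ b - 0.5 * diag * lam @ lam)

    lam = np.zeros(n_j) if lam0 is None else np.array(lam0, dtype=float)
    scale = max(1.0, float(np.max(np.abs(b))))
    gv = g(lam)
    it = 0
    while np.max(np.abs(gv)) > tol * scale:
        if it >= max_iter:
            raise SolverError(
                f"dual Newton did not converge in {max_iter} iterations "
                f"(residual {np.max(np.abs(gv)):.3g})"
            )
        f = wm2 * (A.T @ lam)
        interior = (f > 0.0) & (f < problem.f_iso)
        D = np.where(interior, wm2, 0.0)
        J = (A * D) @ A.T + diag * np.eye(n_j)
        step = np.linalg.solve(J, -gv)
        # Armijo ascent on the dual objective: grad q = -g, so the Newton
        # direction is an ascent direction and damped steps always make
        # progress on the concave piecewise-quadratic dual.
        q0 = dual_value(lam)
        slope = float(-gv @ step)  # grad q . step > 0
        t_ls, ok = 1.0, False
        for _ in range(60):
            cand = lam + t_ls * step
            if dual_value(cand) >= q0 + 1e-4 * t_ls * slope - 1e-14 * max(1.0, abs(q0)):
                lam, gv, ok = cand, g(cand), True
                break
            t_ls *= 0.5
        if not ok:  # pragma: no cover - safeguarded exit
            raise SolverError("line search stalled in dual Newton iteration")
        it += 1

    f = primal(lam)
    r = dr * lam
    R = dres * lam if problem.residual_weight is not None else np.zeros(n_j)

    # KKT verification: stationarity for interior forces, sign conditions at
    # the bounds, and the already-enforced primal feasibility.
    grad = 2.0 * f / problem.muscle_weights**2 - A.T @ lam
    at_lower = f <= 0.0
    at_upper = f >= problem.f_iso
    stat = np.where(at_lower, np.minimum(grad, 0.0), np.where(at_upper, np.maximum(grad, 0.0), grad))
    kkt = max(float(np.max(np.abs(stat))) if stat.size else 0.0, float(np.max(np.abs(gv))) / scale)
    if kkt > kkt_tol:
        raise SolverError(f"KKT residual {kkt:.3g} exceeds tolerance {kkt_tol:.3g}")

    return FrameSolution(
        forces=f,
        reserves=r,
        residuals=R,
        objective=_objective(problem, f, r, R),
        kkt_residual=kkt,
        iterations=it,
        multipliers=lam,
    )


@dataclass
class MuscleSolution:
    """Per-frame forces, reserves and residuals over a full trial.

    ``forces`` is frames x muscles in the order of ``muscle_keys``;
    ``reserves``/``residuals`` are frames x joints in ``joint_order``.
    """

    muscle_keys: list
    joint_order: list
    forces: np.ndarray
    reserves: np.ndarray
    residuals: np.ndarray
    objective: np.ndarray
    kkt_residual: np.ndarray

    def force(self, name: str, side: str) -> np.ndarray:
        return self.forces[:, self.muscle_keys.index(f"{name}_{side[0]}")]


def frame_problems(
    trial: GaitTrial,
    decomposition: HipTorqueDecomposition | None,
    spec: MuscleModelSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Target-moment matrix (frames x joints) and the arm matrix.

    Hip targets come from the exoskeleton decomposition's residual
    biological moment (or the baseline when ``decomposition`` is None, the
    no-device condition); knee and ankle targets are always the baseline
    moments — the device spans only the hips.
    """
    joints = spec.joints
    n = trial.n_samples
    targets = np.empty((n, len(joints)))
    for col, (joint, side) in enumerate(joints):
        if joint == "hip" and decomposition is not None:
            targets[:, col] = decomposition.tau_bio[side]
        else:
            targets[:, col] = trial.moments[(joint, side)]
    return targets, moment_arm_matrix(spec)


def solve_trial(
    trial: GaitTrial,
    decomposition: HipTorqueDecomposition | None,
    spec: MuscleModelSpec,
    tol: float = 1e-10,
    kkt_tol: float = 1e-8,
) -> MuscleSolution:
    """Solve the redundancy QP at every sample of a trial."""
    targets, A = frame_problems(trial, decomposition, spec)
    n, n_m = trial.n_samples, len(spec.muscles)
    n_j = len(spec.joints)
    sol = MuscleSolution(
        muscle_keys=spec.muscle_keys,
        joint_order=list(spec.joints),
        forces=np.empty((n, n_m)),
        reserves=np.empty((n, n_j)),
        residuals=np.empty((n, n_j)),
        objective=np.empty(n),
        kkt_residual=np.empty(n),
    )
    base = FrameProblem(
        targets=targets[0],
        arm_matrix=A,
        f_iso=spec.f_iso(),
        muscle_weights=spec.weights(),
        reserve_weight=spec.reserve_weight,
        residual_weight=spec.residual_weight if spec.residuals_enabled else None,
    )
    lam = None
    for k in range(n):
        base.targets = targets[k]
        try:
            fs = solve_frame(base, tol=tol, kkt_tol=kkt_tol, lam0=lam)
        except (SolverError, ValueError) as exc:
            raise SolverError(f"frame {k} (t={trial.time[k]:.4f}s): {exc}") from exc
        # Warm start from the previous frame's multipliers: targets move
        # slowly along the stride, and the algorithm stays deterministic.
        lam = fs.multipliers
        sol.forces[k] = fs.forces
        sol.reserves[k] = fs.reserves
        sol.residuals[k] = fs.residuals
        sol.objective[k] = fs.objective
        sol.kkt_residual[k] = fs.kkt_residual
    return sol
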