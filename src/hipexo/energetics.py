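"""Metabolic-cost proxy for the reduced muscle model.

Full muscle-energetics models partition heat by fibre shortening state and
need Hill-type internal states this reduced frame does not carry.  The
pluggable proxy implemented here keeps the two features that drive the
stiffness-sweep behaviour: an activation-heat term quadratic in normalized
force, ``c_h * f_iso_i * a_i^2`` with ``a_i = f_i / f_iso_i``, and positive
mechanical work converted at a fixed efficiency, ``max(0, P_i) / eta``
where ``P_i = f_i * sum_j arm[j,i] * qdot_j`` is the muscle's joint power
under the flexion-positive arm convention.  The whole-body rate is the
stride integral of the summed instantaneous power divided by stride period
and body mass (W/kg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exo_spring import stride_integral
from .gait_synth import GaitTrial
from .muscle_model import MuscleModelSpec, moment_arm_matrix
from .static_opt import MuscleSolution

__all__ = [
    "EnergeticsConfig",
    "instantaneous_metabolic_power",
    "metabolic_power_series",
    "metabolic_rate",
]


@dataclass(frozen=True)
class EnergeticsConfig:
    """Proxy parameters.

    ``heat_coefficient`` (W/N) scales activation heat per unit isometric
    force; ``efficiency`` is the classic ~0.25 conversion of positive
    mechanical work to metabolic cost.
    """

    heat_coefficient: float = 0.5
    efficiency: float = 0.25
    model_name: str = "activation2-positive-work"

    def __post_init__(self):
        if self.heat_coefficient < 0:
            raise ValueError("heat_coefficient must be >= 0")
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must lie in (0, 1]")


def instantaneous_metabolic_power(
    forces: np.ndarray,
    arm_matrix: np.ndarray,
    qdot: np.ndarray,
    f_iso: np.ndarray,
    config: EnergeticsConfig | None = None,
) -> float:
    """Summed metabolic power of one frame (watts)."""
    config = config or EnergeticsConfig()
    forces = np.asarray(forces, dtype=float)
    if np.any(forces < 0):
        raise ValueError("muscle forces must be non-negative")
    a = forces / f_iso
    heat = config.heat_coefficient * f_iso * a**2
    power = forces * (arm_matrix.T @ qdot)
    work = np.maximum(0.0, power) / config.efficiency
    return float(np.sum(heat + work))


def metabolic_power_series(
    trial: GaitTrial,
    solution: MuscleSolution,
    spec: MuscleModelSpec,
    config: EnergeticsConfig | None = None,
) -> np.ndarray:
    """Instantaneous whole-body metabolic power at every sample (watts)."""
    config = config or EnergeticsConfig()
    if solution.forces.shape[0] != trial.n_samples:
        raise ValueError("solution and trial grids differ")
    A = moment_arm_matrix(spec)
    qdot = np.column_stack([trial.velocities[key] for key in spec.joints])
    f_iso = spec.f_iso()
    a2 = (solution.forces / f_iso) ** 2
    heat = a2 @ (config.heat_coefficient * f_iso)
    power = solution.forces * (qdot @ A)
    work = np.maximum(0.0, power).sum(axis=1) / config.efficiency
    return heat + work


def metabolic_rate(
    trial: GaitTrial,
    solution: MuscleSolution,
    config: EnergeticsConfig | None = None,
    spec: MuscleModelSpec | None = None,
    power: np.ndarray | None = None,
) -> float:
    """Normalized metabolic rate (W/kg): stride-average power over body mass.

    Either pass ``spec`` (power computed from the solution) or a
    precomputed instantaneous ``power`` series.
    """
    if power is None:
        if spec is None:
            raise ValueError("either spec or a precomputed power series is required")
        power = metabolic_power_series(trial, solution, spec, config)
    if power.shape[0] != trial.n_samples:
        raise ValueError("power series and trial grids differ")
    total = stride_integral(power, trial.time, trial.stride_period)
    return float(total / (trial.stride_period * trial.mass))
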