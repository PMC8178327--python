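"""Scalar gait and effort indices.

Stride-averaged quantities (mass-normalized absolute joint moment and
muscle force), the squared-normalized-force fatigue/effort integrals — over
all muscles, and restricted to the antagonistic mono-articular hip pair
(Psoas, Gluteus Maximus) — and the kinematic triple:

    A  = max left-hip angle over the stride
    B  = min right-hip angle over the stride
    RM = |A - B|          range of motion (rad)
    SM = |A + B|^-1       symmetry of motion (1/rad)
    RS = RM * SM          the kinematic predictor of metabolic benefit

SM diverges for a perfectly symmetric gait (A = -B); that is reported as an
error rather than capped, since downstream regressions must know the index
is undefined there.  For rhythmic gait the triple is stride-invariant; for
multi-stride recordings compute it per stride and average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exo_spring import stride_integral
from .gait_synth import GaitTrial
from .muscle_model import MONO_HIP_PAIR, MuscleModelSpec
from .static_opt import MuscleSolution

__all__ = [
    "PerfectSymmetryError",
    "IndexReport",
    "average_abs_moment",
    "average_force",
    "fatigue_all",
    "fatigue_mono",
    "kinematic_indices",
    "kinematic_indices_from_angles",
]


class PerfectSymmetryError(ValueError):
    """|A + B| is below tolerance: the symmetry index SM is unbounded."""


@dataclass(frozen=True)
class IndexReport:
    """All scalar indices of one (subject, spring-coefficient) cell."""

    subject_id: str
    alpha: float
    metabolic_rate: float                     # W/kg
    avg_abs_moment: dict                      # joint -> N*m/kg (mean of sides)
    avg_force: dict                           # muscle key -> N/kg
    fatigue_all: float
    fatigue_mono: float
    rm: float                                 # rad
    sm: float                                 # 1/rad
    rs: float

    def __post_init__(self):
        if self.fatigue_all < 0 or self.fatigue_mono < 0:
            raise ValueError("fatigue indices must be >= 0")
        if not np.isclose(self.rs, self.rm * self.sm, rtol=1e-12, atol=0):
            raise ValueError("RS must equal RM * SM")


def average_abs_moment(moment: np.ndarray, time: np.ndarray, period: float, mass: float) -> float:
    """Stride-averaged absolute moment per unit mass, N*m/kg."""
    if mass <= 0:
        raise ValueError("mass must be > 0")
    return stride_integral(np.abs(moment), time, period) / (period * mass)


def average_force(force: np.ndarray, time: np.ndarray, period: float, mass: float) -> float:
    """Stride-averaged muscle force per unit mass, N/kg (forces are >= 0)."""
    if mass <= 0:
        raise ValueError("mass must be > 0")
    return stride_integral(force, time, period) / (period * mass)


def fatigue_all(solution: MuscleSolution, spec: MuscleModelSpec, time: np.ndarray, period: float) -> float:
    """Stride-average of the summed squared normalized forces, all muscles."""
    a2 = (solution.forces / spec.f_iso()) ** 2
    return stride_integral(a2.sum(axis=1), time, period) / period


def fatigue_mono(
    solution: MuscleSolution,
    spec: MuscleModelSpec,
    time: np.ndarray,
    period: float,
    side: str = "right",
) -> float:
    """Fatigue restricted to the antagonistic mono-articular hip pair."""
    total = np.zeros(solution.forces.shape[0])
    for name in MONO_HIP_PAIR:
        muscle = spec.find(name, side)  # KeyError if absent from the spec
        total += (solution.force(name, side) / muscle.f_iso) ** 2
    return stride_integral(total, time, period) / period


def kinematic_indices_from_angles(
    q_hip_left: np.ndarray,
    q_hip_right: np.ndarray,
    eps: float = 1e-6,
) -> tuple[float, float, float]:
    """(RM, SM, RS) from one stride of bilateral hip angles."""
    a = float(np.max(q_hip_left))
    b = float(np.min(q_hip_right))
    s = abs(a + b)
    if s <= eps:
        raise PerfectSymmetryError(
            f"|A + B| = {s:.3g} rad <= {eps:.3g}: symmetry index is unbounded"
        )
    rm = abs(a - b)
    sm = 1.0 / s
    return rm, sm, rm * sm


def kinematic_indices(trial: GaitTrial, eps: float = 1e-6) -> tuple[float, float, float]:
    """(RM, SM, RS) of a trial's hip channels."""
    return kinematic_indices_from_angles(
        trial.angles[("hip", "left")], trial.angles[("hip", "right")], eps=eps
    )
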