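"""Reduced musculoskeletal frame: muscles, moment arms, reserve actuators.

The default roster keeps the nine muscle branches per leg that dominate
sagittal running — Psoas and Gluteus Maximus (the antagonistic
mono-articular hip pair), Rectus Femoris and Semimembranosus (bi-articular
hip muscles), Vastus Lateralis, Biceps Femoris short head, Gastrocnemius
Medialis, Tibialis Anterior and Soleus — with signed constant moment arms
on {hip, knee, ankle} per side and one reserve actuator per modelled joint.
Reserve (and optional residual) weights are small against the joint-moment
scale, so the optimizer uses them only when muscles cannot balance a
moment.

This is an explicit reduction from full-body models (tens of muscles, many
degrees of freedom) to 18 muscles and 6 moment channels: it preserves the
named muscles, their mono-/bi-articular structure and antagonism, not
anatomical fidelity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .gait_synth import JOINTS, SIDES

__all__ = [
    "MuscleDef",
    "MuscleModelSpec",
    "default_model",
    "load_model",
    "moment_arm_matrix",
]

MAX_ARM_M = 0.12
HIP_MUSCLES = ("psoas", "glut_max", "rect_fem", "semimem")
MONO_HIP_PAIR = ("psoas", "glut_max")


@dataclass(frozen=True)
class MuscleDef:
    """One muscle branch on one side.

    ``arms`` maps spanned joints to signed moment arms (m, positive =
    contributes a flexion moment); ``arm_poly`` optionally replaces a
    constant arm with polynomial coefficients in the joint angle
    (ascending order, radians).  ``weight`` is the force normaliser in the
    static-optimization objective; the default ``weight == f_iso`` makes
    each term the squared normalized force.
    """

    name: str
    side: str
    arms: dict
    f_iso: float
    weight: float | None = None
    arm_poly: dict | None = None

    def __post_init__(self):
        if self.weight is None:
            object.__setattr__(self, "weight", self.f_iso)

    def validate(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"{self.name}: side must be one of {SIDES}, got {self.side!r}")
        if self.f_iso <= 0:
            raise ValueError(f"{self.name}: f_iso must be > 0")
        if self.weight <= 0:
            raise ValueError(f"{self.name}: weight must be > 0")
        if not 1 <= len(self.arms) <= 2:
            raise ValueError(f"{self.name}: must span 1 or 2 joints, spans {len(self.arms)}")
        for joint, arm in self.arms.items():
            if joint not in JOINTS:
                raise ValueError(f"{self.name}: unknown joint {joint!r}")
            if abs(arm) > MAX_ARM_M:
                raise ValueError(f"{self.name}: |moment arm| {arm} m exceeds {MAX_ARM_M} m")

    @property
    def key(self) -> str:
        return f"{self.name}_{self.side[0]}"

    def arm_at(self, joint: str, angle: float | None = None) -> float:
        if self.arm_poly and joint in self.arm_poly and angle is not None:
            return float(np.polynomial.polynomial.polyval(angle, self.arm_poly[joint]))
        return float(self.arms[joint])


@dataclass
class MuscleModelSpec:
    """Muscle roster plus reserve/residual actuators for both legs."""

    muscles: list
    reserve_weight: float = 1.0
    residual_weight: float = 1.0
    residuals_enabled: bool = False

    @property
    def joints(self) -> list:
        return [(j, s) for s in SIDES for j in JOINTS]

    @property
    def muscle_keys(self) -> list:
        return [m.key for m in self.muscles]

    def muscles_on(self, side: str) -> list:
        return [m for m in self.muscles if m.side == side]

    def find(self, name: str, side: str) -> MuscleDef:
        for m in self.muscles:
            if m.name == name and m.side == side:
                return m
        raise KeyError(f"muscle {name!r} ({side}) not in model")

    def f_iso(self) -> np.ndarray:
        return np.array([m.f_iso for m in self.muscles])

    def weights(self) -> np.ndarray:
        return np.array([m.weight for m in self.muscles])

    def validate(self) -> None:
        if self.reserve_weight <= 0 or self.residual_weight <= 0:
            raise ValueError("reserve and residual weights must be > 0")
        seen = set()
        for m in self.muscles:
            m.validate()
            if m.key in seen:
                raise ValueError(f"duplicate muscle {m.key}")
            seen.add(m.key)
        # Reserves are bidirectional, so with one reserve per joint every
        # joint always has flexor and extensor pathways; the check below
        # additionally reports joints with one-sided muscular coverage.
        for joint, side in self.joints:
            arms = [m.arms[joint] for m in self.muscles if m.side == side and joint in m.arms]
            if not arms:
                continue
            if not (any(a > 0 for a in arms) and any(a < 0 for a in arms)):
                raise ValueError(
                    f"joint ({joint}, {side}) lacks an antagonistic muscle pair; "
                    "only the reserve actuator opposes its muscles"
                )

    def to_dict(self) -> dict:
        return {
            "muscles": [
                {
                    "name": m.name,
                    "side": m.side,
                    "arms": dict(m.arms),
                    "f_iso": m.f_iso,
                    "weight": m.weight,
                    **({"arm_poly": {k: list(v) for k, v in m.arm_poly.items()}} if m.arm_poly else {}),
                }
                for m in self.muscles
            ],
            "reserve_weight": self.reserve_weight,
            "residual_weight": self.residual_weight,
            "residuals_enabled": self.residuals_enabled,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "MuscleModelSpec":
        muscles = [
            MuscleDef(
                name=md["name"],
                side=md["side"],
                arms=dict(md["arms"]),
                f_iso=float(md["f_iso"]),
                weight=float(md["weight"]) if md.get("weight") is not None else None,
                arm_poly={k: list(map(float, v)) for k, v in md["arm_poly"].items()}
                if md.get("arm_poly")
                else None,
            )
            for md in d["muscles"]
        ]
        spec = cls(
            muscles=muscles,
            reserve_weight=float(d.get("reserve_weight", 1.0)),
            residual_weight=float(d.get("residual_weight", 1.0)),
            residuals_enabled=bool(d.get("residuals_enabled", False)),
        )
        spec.validate()
        return spec


def _default_table() -> dict:
    text = resources.files("hipexo.data").joinpath("default_muscles.yaml").read_text()
    return yaml.safe_load(text)


def default_model() -> MuscleModelSpec:
    """The bundled 9-muscle-per-leg model with one reserve per joint."""
    table = _default_table()
    muscles = [
        MuscleDef(name=md["name"], side=side, arms=dict(md["arms"]), f_iso=float(md["f_iso"]))
        for side in SIDES
        for md in table["muscles"]
    ]
    spec = MuscleModelSpec(
        muscles=muscles,
        reserve_weight=float(table["reserve_weight"]),
        residual_weight=float(table["residual_weight"]),
    )
    spec.validate()
    return spec


def load_model(path) -> MuscleModelSpec:
    """Load and validate a muscle model spec from YAML."""
    with open(path) as fh:
        return MuscleModelSpec.from_dict(yaml.safe_load(fh))


def moment_arm_matrix(spec: MuscleModelSpec, frame: dict | None = None) -> np.ndarray:
    """Signed moment-arm matrix, joints x muscles (metres).

    Rows follow ``spec.joints``; columns follow ``spec.muscles``.  ``frame``
    maps ``(joint, side)`` to the joint angle (rad, within +/- pi) and only
    matters for muscles configured with polynomial arms; the default
    constant-arm model is frame-independent.
    """
    if frame is not None:
        for key, angle in frame.items():
            if key[0] not in JOINTS:
                raise ValueError(f"unknown joint {key!r}")
            if abs(angle) > np.pi:
                raise ValueError(f"angle for {key} outside +/- pi: {angle}")
    joints = spec.joints
    mat = np.zeros((len(joints), len(spec.muscles)))
    for col, m in enumerate(spec.muscles):
        for joint in m.arms:
            row = joints.index((joint, m.side))
            angle = frame.get((joint, m.side)) if frame else None
            mat[row, col] = m.arm_at(joint, angle)
    return mat
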