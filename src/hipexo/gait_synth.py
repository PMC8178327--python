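"""Synthetic running-gait generation.

Produces stride-periodic bilateral joint kinematics and baseline joint
moments for a sagittal-plane lower-limb model (hip, knee, ankle per side).
All waveforms are finite Fourier series in stride phase, which guarantees
exact periodicity and analytic time derivatives; per-subject parameters
control hip range of motion, left/right symmetry, moment amplitude, body
mass and stride period, so a cohort can be drawn with the heterogeneity the
downstream kinematic-index regression assumes.

Conventions: angles in radians, flexion positive (ankle dorsiflexion
positive); moments in newton-metres, flexion positive; the stride phase
``phi = t / T`` runs over ``[0, 1)`` on a uniform grid that excludes the
endpoint ``T`` (the sample at ``T`` would duplicate the one at ``0``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

JOINTS = ("hip", "knee", "ankle")
SIDES = ("left", "right")

__all__ = [
    "JOINTS",
    "SIDES",
    "ParameterError",
    "FourierSeries",
    "SubjectParams",
    "GaitTrial",
    "CohortRanges",
    "default_cohort_ranges",
    "make_subject",
    "make_cohort",
]


class ParameterError(ValueError):
    """A subject or cohort parameter violates its declared constraint."""

    def __init__(self, fld: str, message: str):
        self.field = fld
        super().__init__(f"{fld}: {message}")


@dataclass(frozen=True)
class FourierSeries:
    """Finite Fourier series ``y(phi) = mean + sum_k a_k cos(2 pi k phi) + b_k sin(2 pi k phi)``."""

    mean: float
    cos: np.ndarray
    sin: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "cos", np.atleast_1d(np.asarray(self.cos, dtype=float)))
        object.__setattr__(self, "sin", np.atleast_1d(np.asarray(self.sin, dtype=float)))
        if self.cos.shape != self.sin.shape:
            raise ValueError("cos and sin coefficient arrays must have the same length")

    @property
    def n_harmonics(self) -> int:
        return self.cos.size

    def __call__(self, phi: np.ndarray) -> np.ndarray:
        phi = np.asarray(phi, dtype=float)
        k = np.arange(1, self.n_harmonics + 1)
        ang = 2.0 * np.pi * np.multiply.outer(phi, k)
        return self.mean + np.cos(ang) @ self.cos + np.sin(ang) @ self.sin

    def derivative(self, period: float) -> "FourierSeries":
        """Time derivative for a series sampled on phase ``phi = t/period``."""
        k = np.arange(1, self.n_harmonics + 1)
        w = 2.0 * np.pi * k / period
        return FourierSeries(mean=0.0, cos=w * self.sin, sin=-w * self.cos)

    def shifted(self, dphi: float) -> "FourierSeries":
        """The same waveform advanced in phase: ``y'(phi) = y(phi - dphi)``."""
        k = np.arange(1, self.n_harmonics + 1)
        c, s = np.cos(2.0 * np.pi * k * dphi), np.sin(2.0 * np.pi * k * dphi)
        return FourierSeries(
            mean=self.mean,
            cos=c * self.cos - s * self.sin,
            sin=s * self.cos + c * self.sin,
        )

    def __add__(self, offset: float) -> "FourierSeries":
        return FourierSeries(self.mean + float(offset), self.cos, self.sin)


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject generator parameters.

    ``hip_flexion_peak`` / ``hip_extension_min`` set the extrema of the hip
    waveform (before the left-side ``symmetry_offset`` is added), so the
    range-of-motion and symmetry indices of the emitted trial are controlled
    directly.  ``phase_lag`` is the left-relative-to-right shift as a stride
    fraction (0.5 = antiphase).  ``noise_sd`` perturbs Fourier coefficients,
    never samples, so noisy trials remain exactly periodic.
    """

    hip_flexion_peak: float = 0.52      # rad
    hip_extension_min: float = -0.35    # rad
    symmetry_offset: float = 0.0        # rad, added to the left hip channel
    phase_lag: float = 0.5              # stride fraction
    knee_amplitude: float = 0.9         # rad
    ankle_amplitude: float = 0.35       # rad
    moment_amplitude: float = 65.0      # N*m, hip moment scale
    moment_harmonics: int = 2
    noise_sd: float = 0.0               # rad, on Fourier coefficients
    mass: float = 70.9                  # kg
    stride_period: float = 0.7          # s
    n_samples: int = 200

    def validate(self) -> None:
        if not np.isfinite(self.hip_flexion_peak) or not np.isfinite(self.hip_extension_min):
            raise ParameterError("hip_flexion_peak", "hip extrema must be finite")
        if self.hip_flexion_peak <= self.hip_extension_min:
            raise ParameterError(
                "hip_flexion_peak",
                f"must exceed hip_extension_min ({self.hip_flexion_peak} <= {self.hip_extension_min})",
            )
        if not 0.0 < self.phase_lag < 1.0:
            raise ParameterError("phase_lag", f"must lie in (0, 1), got {self.phase_lag}")
        if self.noise_sd < 0.0:
            raise ParameterError("noise_sd", f"must be >= 0, got {self.noise_sd}")
        if self.mass <= 0.0:
            raise ParameterError("mass", f"must be > 0, got {self.mass}")
        if self.stride_period <= 0.0:
            raise ParameterError("stride_period", f"must be > 0, got {self.stride_period}")
        if self.knee_amplitude < 0.0:
            raise ParameterError("knee_amplitude", f"must be >= 0, got {self.knee_amplitude}")
        if self.ankle_amplitude < 0.0:
            raise ParameterError("ankle_amplitude", f"must be >= 0, got {self.ankle_amplitude}")
        if self.moment_amplitude < 0.0:
            raise ParameterError("moment_amplitude", f"must be >= 0, got {self.moment_amplitude}")
        if self.moment_harmonics < 1:
            raise ParameterError("moment_harmonics", f"must be >= 1, got {self.moment_harmonics}")
        if self.n_samples < 50:
            raise ParameterError("n_samples", f"must be >= 50, got {self.n_samples}")


@dataclass
class GaitTrial:
    """One subject's stride of bilateral kinematics and baseline moments.

    ``angles``, ``velocities`` and ``moments`` are keyed ``(joint, side)``
    with values sampled on ``time``; ``waveforms``/``moment_waveforms`` keep
    the underlying Fourier series when the trial was synthesised, enabling
    exact periodicity checks and analytic derivatives.
    """

    subject_id: str
    time: np.ndarray
    stride_period: float
    mass: float
    angles: dict
    velocities: dict
    moments: dict
    waveforms: dict | None = None
    moment_waveforms: dict | None = None

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return self.stride_period / self.n_samples

    def validate(self, periodicity_tol: float = 1e-6) -> None:
        t = self.time
        if t.ndim != 1 or t.size < 50:
            raise ValueError("time grid must be 1-D with at least 50 samples")
        dts = np.diff(t)
        if np.any(dts <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.allclose(dts, self.dt, rtol=0, atol=1e-9 * self.stride_period):
            raise ValueError("time grid must be uniform with spacing T/N")
        if self.mass <= 0 or self.stride_period <= 0:
            raise ValueError("mass and stride_period must be positive")
        for key in self.angles:
            n = self.angles[key].size
            if n != t.size or self.velocities[key].size != n or self.moments[key].size != n:
                raise ValueError(f"channel {key} length mismatch with time grid")
        err = self.periodicity_error()
        if err > periodicity_tol:
            raise ValueError(f"periodicity violated: max |q(0) - q(T)| = {err:.3g} rad")

    def periodicity_error(self) -> float:
        """Max over channels of |q(0) - q(T)| for the underlying waveform.

        With stored Fourier waveforms this is exact (and identically zero up
        to rounding).  For trials loaded from files the wrap-around is
        estimated by extrapolating the last sample one step with its
        velocity, a second-order surrogate.
        """
        if self.waveforms is not None:
            errs = [abs(w(0.0) - w(1.0)) for w in self.waveforms.values()]
            return float(max(errs))
        errs = []
        for key, q in self.angles.items():
            q_wrap = q[-1] + self.velocities[key][-1] * self.dt
            errs.append(abs(q[0] - q_wrap))
        return float(max(errs))

    def channels(self) -> Iterator[tuple[str, str]]:
        return iter(self.angles.keys())


# Base shapes: fixed harmonic mixtures in stride phase giving plausible
# sagittal running profiles; subject parameters scale and shift them.
# The hip-moment first harmonic is deliberately anti-aligned with the hip
# angle (extensor demand at peak flexion) up to a misalignment angle DELTA,
# so the coupling spring's torque is useful but not a perfect match.
_HIP_SHAPE = FourierSeries(0.0, [1.0, 0.12 * np.cos(0.8)], [0.0, -0.12 * np.sin(0.8)])
_DELTA = 0.35  # rad, hip-moment vs hip-angle first-harmonic misalignment


def _hip_angle_series(params: SubjectParams) -> FourierSeries:
    phi_dense = np.linspace(0.0, 1.0, 2048, endpoint=False)
    s = _HIP_SHAPE(phi_dense)
    s_max, s_min = s.max(), s.min()
    amp = (params.hip_flexion_peak - params.hip_extension_min) / (s_max - s_min)
    offset = params.hip_flexion_peak - amp * s_max
    return FourierSeries(offset + amp * _HIP_SHAPE.mean, amp * _HIP_SHAPE.cos, amp * _HIP_SHAPE.sin)


def _knee_angle_series(params: SubjectParams) -> FourierSeries:
    a = params.knee_amplitude
    return FourierSeries(
        0.45 * a,
        [0.35 * a * np.cos(2.9), 0.18 * a * np.cos(1.2)],
        [-0.35 * a * np.sin(2.9), -0.18 * a * np.sin(1.2)],
    )


def _ankle_angle_series(params: SubjectParams) -> FourierSeries:
    a = params.ankle_amplitude
    return FourierSeries(
        0.1 * a,
        [0.6 * a * np.cos(2.2), 0.25 * a * np.cos(0.3)],
        [-0.6 * a * np.sin(2.2), -0.25 * a * np.sin(0.3)],
    )


def _moment_series(params: SubjectParams, joint: str) -> FourierSeries:
    """Baseline (no-exoskeleton) joint moment waveform, right side."""
    m = params.moment_amplitude
    nh = params.moment_harmonics
    if joint == "hip":
        # Biphasic: dominant first harmonic anti-aligned with hip flexion,
        # a second harmonic, and a small offset; >= 2 sign changes/stride.
        cos_c = [-0.85 * m * np.cos(_DELTA), 0.30 * m * np.cos(0.5 - np.pi / 2)]
        sin_c = [0.85 * m * np.sin(_DELTA), -0.30 * m * np.sin(0.5 - np.pi / 2)]
        mean = 0.05 * m
    elif joint == "knee":
        # Predominantly extensor (negative) in stance.
        cos_c = [-0.45 * 0.85 * m * np.cos(-0.6), -0.15 * 0.85 * m * np.cos(0.9)]
        sin_c = [-0.45 * 0.85 * m * np.sin(0.6), 0.15 * 0.85 * m * np.sin(0.9)]
        mean = -0.40 * 0.85 * m
    elif joint == "ankle":
        # Predominantly plantarflexor (negative) with a dorsiflexion phase.
        cos_c = [-0.48 * 1.1 * m * np.cos(-1.1), -0.14 * 1.1 * m]
        sin_c = [-0.48 * 1.1 * m * np.sin(1.1), 0.0]
        mean = -0.38 * 1.1 * m
    else:  # pragma: no cover - internal
        raise ValueError(joint)
    if nh > 2:
        cos_c += [0.08 * m * ((-1) ** k) for k in range(3, nh + 1)]
        sin_c += [0.0] * (nh - 2)
    else:
        cos_c, sin_c = cos_c[:nh], sin_c[:nh]
    return FourierSeries(mean, cos_c, sin_c)


def _perturb(series: FourierSeries, sd: float, rng: np.random.Generator) -> FourierSeries:
    if sd == 0.0:
        return series
    return FourierSeries(
        series.mean,
        series.cos + rng.normal(0.0, sd, series.n_harmonics),
        series.sin + rng.normal(0.0, sd, series.n_harmonics),
    )


def make_subject(params: SubjectParams | None = None, seed: int = 0, subject_id: str | None = None) -> GaitTrial:
    """Generate one stride-periodic gait trial.

    The left channels are the right waveforms phase-shifted by
    ``phase_lag`` strides; the left hip additionally receives the constant
    ``symmetry_offset``.  Velocities are the analytic derivatives of the
    Fourier series.  Identical ``(params, seed)`` give bit-identical trials.
    """
    params = params or SubjectParams()
    params.validate()
    rng = np.random.default_rng(seed)

    right_angle = {
        "hip": _hip_angle_series(params),
        "knee": _knee_angle_series(params),
        "ankle": _ankle_angle_series(params),
    }
    right_moment = {j: _moment_series(params, j) for j in JOINTS}

    waveforms: dict = {}
    moment_waveforms: dict = {}
    for joint in JOINTS:
        q_r = _perturb(right_angle[joint], params.noise_sd, rng)
        q_l = _perturb(right_angle[joint], params.noise_sd, rng).shifted(params.phase_lag)
        if joint == "hip":
            q_l = q_l + params.symmetry_offset
        waveforms[(joint, "right")] = q_r
        waveforms[(joint, "left")] = q_l
        # Moment noise scales with the moment amplitude so noise_sd keeps
        # a single (angular) unit at the interface.
        m_sd = params.noise_sd * params.moment_amplitude
        moment_waveforms[(joint, "right")] = _perturb(right_moment[joint], m_sd, rng)
        moment_waveforms[(joint, "left")] = _perturb(right_moment[joint], m_sd, rng).shifted(params.phase_lag)

    T, N = params.stride_period, params.n_samples
    time = np.arange(N) * (T / N)
    phi = time / T
    angles = {k: w(phi) for k, w in waveforms.items()}
    velocities = {k: w.derivative(T)(phi) for k, w in waveforms.items()}
    moments = {k: w(phi) for k, w in moment_waveforms.items()}

    return GaitTrial(
        subject_id=subject_id or f"S{seed}",
        time=time,
        stride_period=T,
        mass=params.mass,
        angles=angles,
        velocities=velocities,
        moments=moments,
        waveforms=waveforms,
        moment_waveforms=moment_waveforms,
    )


@dataclass(frozen=True)
class CohortRanges:
    """Uniform sampling ranges ``(low, high)`` for SubjectParams fields.

    Degenerate ranges (``low == high``) pin a field.  Defaults span a
    heterogeneous cohort: hip ranges of motion ~0.76-1.08 rad, left/right
    symmetry offsets up to ~11 degrees (the dominant inter-subject axis, so
    the symmetry index varies widely while |A + B| stays bounded away from
    zero), and a tight antiphase phase lag as in steady running.
    """

    hip_flexion_peak: tuple = (0.46, 0.58)
    hip_extension_min: tuple = (-0.40, -0.30)
    symmetry_offset: tuple = (-0.02, 0.20)
    phase_lag: tuple = (0.49, 0.51)
    knee_amplitude: tuple = (0.8, 1.0)
    ankle_amplitude: tuple = (0.3, 0.4)
    moment_amplitude: tuple = (55.0, 75.0)
    noise_sd: tuple = (0.0, 0.0)
    mass: tuple = (63.9, 77.9)
    stride_period: tuple = (0.65, 0.75)

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            lo, hi = getattr(self, f.name)
            if hi < lo:
                raise ParameterError(f.name, f"empty range ({lo}, {hi})")


def default_cohort_ranges() -> CohortRanges:
    return CohortRanges()


def make_cohort(
    n: int = 7,
    ranges: CohortRanges | None = None,
    seed: int = 0,
    base_params: SubjectParams | None = None,
) -> list[GaitTrial]:
    """Draw ``n`` subjects with independent uniform parameters.

    The cohort is a pure function of ``(n, ranges, seed)``: parameters and
    per-subject child seeds all derive from one seeded generator.
    """
    if n < 1:
        raise ParameterError("n", f"must be >= 1, got {n}")
    ranges = ranges or default_cohort_ranges()
    ranges.validate()
    base = base_params or SubjectParams()
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n):
        draw = {
            f.name: float(rng.uniform(*getattr(ranges, f.name)))
            for f in dataclasses.fields(ranges)
        }
        params = dataclasses.replace(base, **draw)
        child_seed = int(rng.integers(0, 2**31 - 1))
        trials.append(make_subject(params, seed=child_seed, subject_id=f"S{i + 1:02d}"))
    return trials
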