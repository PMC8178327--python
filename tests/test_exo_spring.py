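import numpy as np
import pytest

import hipexo as hx
from hipexo.exo_spring import (
    DegenerateCalibrationError,
    calibrate_kinv,
    stride_integral,
)


def _simple_trial(q_left, q_right, tau_left, tau_right, period=1.0):
    """Minimal hip-only trial on a uniform grid (knee/ankle flat)."""
    n = len(q_right)
    time = np.arange(n) * (period / n)
    zeros = np.zeros(n)
    angles, velocities, moments = {}, {}, {}
    for joint in ("hip", "knee", "ankle"):
        for side in ("left", "right"):
            angles[(joint, side)] = zeros
            velocities[(joint, side)] = zeros
            moments[(joint, side)] = zeros
    angles[("hip", "left")] = np.asarray(q_left, dtype=float)
    angles[("hip", "right")] = np.asarray(q_right, dtype=float)
    moments[("hip", "left")] = np.asarray(tau_left, dtype=float)
    moments[("hip", "right")] = np.asarray(tau_right, dtype=float)
    return hx.GaitTrial(
        subject_id="toy",
        time=time,
        stride_period=period,
        mass=70.0,
        angles=angles,
        velocities=velocities,
        moments=moments,
    )


@pytest.fixture
def grid():
    n = 200
    t = np.arange(n) / n
    return t, np.sin(2 * np.pi * t), np.cos(2 * np.pi * t)


class TestDeltaTheta:
    def test_identical_sides_give_zero(self, grid):
        t, s, _ = grid
        tr = _simple_trial(s, s, s, s)
        assert np.array_equal(hx.delta_theta(tr), np.zeros_like(s))

    def test_opposite_sines_double(self, grid):
        t, s, _ = grid
        tr = _simple_trial(s, -s, s, s)
        assert np.allclose(hx.delta_theta(tr), 2 * s, atol=1e-15)

    def test_antiphase_default_trial_has_zero_mean(self, default_trial):
        params = hx.SubjectParams(phase_lag=0.5, symmetry_offset=0.0)
        tr = hx.make_subject(params, seed=2)
        dth = hx.delta_theta(tr)
        mean = stride_integral(dth, tr.time, tr.stride_period) / tr.stride_period
        assert abs(mean) < 1e-10


class TestCalibration:
    def test_exact_proportional_moment_recovers_constant(self, grid):
        t, s, _ = grid
        dth = s
        tau = {"right": 17.3 * dth, "left": -17.3 * dth}
        k = calibrate_kinv(tau, dth, t, 1.0)
        assert k == pytest.approx(17.3, rel=1e-12)

    def test_orthogonal_moment_gives_zero(self, grid):
        t, s, c = grid
        tau = {"right": c, "left": -c}
        assert calibrate_kinv(tau, s, t, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_against_discrete_least_squares_oracle(self, grid):
        t, s, c = grid
        tau_r = 2.0 * s + 0.5 * c
        tau = {"right": tau_r, "left": -tau_r}
        k = calibrate_kinv(tau, s, t, 1.0)
        # independent oracle: plain discrete least squares on stacked sides
        design = np.concatenate([s, -s])
        target = np.concatenate([tau_r, -tau_r])
        (k_ref,), *_ = np.linalg.lstsq(design[:, None], target, rcond=None)
        assert k == pytest.approx(k_ref, rel=1e-10)
        assert k == pytest.approx(2.0, rel=1e-10)

    def test_degenerate_dtheta_raises(self, grid):
        t, s, _ = grid
        with pytest.raises(DegenerateCalibrationError):
            calibrate_kinv({"right": s, "left": -s}, np.zeros_like(s), t, 1.0)

    def test_first_order_optimality(self, default_trial):
        calib = hx.calibrate_trial(default_trial)
        h = 1e-6 * max(1.0, abs(calib.k_inv))
        j0 = _j_of_k(default_trial, calib.k_inv)
        assert _j_of_k(default_trial, calib.k_inv + h) > j0
        assert _j_of_k(default_trial, calib.k_inv - h) > j0


def _j_of_k(trial, k):
    calib = hx.ExoCalibration(k_inv=k, assist_side="right")
    return hx.squared_moment_integral(trial, calib, alpha=1.0)


class TestAssistiveTorque:
    def test_alpha_zero_is_silent(self, grid):
        t, s, _ = grid
        calib = hx.ExoCalibration(k_inv=50.0, alpha=0.0)
        tau = hx.assistive_torque(calib, s)
        assert np.all(tau["left"] == 0.0) and np.all(tau["right"] == 0.0)

    def test_constant_deflection(self):
        calib = hx.ExoCalibration(k_inv=1.0, alpha=1.0)
        tau = hx.assistive_torque(calib, np.full(100, 0.3))
        assert np.allclose(tau["right"], 0.3) and np.allclose(tau["left"], -0.3)

    def test_amplitude_and_antisymmetry(self, grid):
        t, s, _ = grid
        calib = hx.ExoCalibration(k_inv=2.0, alpha=0.6)
        tau = hx.assistive_torque(calib, s)
        assert np.max(np.abs(tau["right"])) == pytest.approx(1.2, rel=1e-3)
        assert np.array_equal(tau["left"], -tau["right"])

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            hx.ExoCalibration(k_inv=1.0, alpha=-0.1)

    def test_linear_range_warning(self):
        calib = hx.ExoCalibration(k_inv=1.0, alpha=1.0)
        with pytest.warns(UserWarning):
            hx.assistive_torque(calib, np.full(10, 1.0), warn_linear_range=True)


class TestResidualMoment:
    def test_alpha_zero_identity(self, default_trial):
        calib = hx.calibrate_trial(default_trial)
        dec = hx.residual_hip_moment(default_trial, calib.with_alpha(0.0))
        for side in ("left", "right"):
            assert np.array_equal(dec.tau_bio[side], default_trial.moments[("hip", side)])
            assert np.all(dec.region[side] == "neutral")

    def test_improvement_label(self):
        n = 100
        tr = _simple_trial(
            np.full(n, 0.4), np.zeros(n), np.full(n, 10.0), np.full(n, 10.0)
        )
        calib = hx.ExoCalibration(k_inv=10.0, alpha=1.0)  # applied right = +4
        dec = hx.residual_hip_moment(tr, calib)
        assert np.allclose(dec.tau_bio["right"], 6.0)
        assert np.all(dec.region["right"] == "improve")

    def test_disruption_label_on_sign_reversal(self):
        n = 100
        tr = _simple_trial(
            np.full(n, 0.4), np.zeros(n), np.full(n, 10.0), np.full(n, 10.0)
        )
        calib = hx.ExoCalibration(k_inv=35.0, alpha=1.0)  # applied right = +14
        dec = hx.residual_hip_moment(tr, calib)
        assert np.allclose(dec.tau_bio["right"], -4.0)
        assert np.all(dec.region["right"] == "disrupt")

    def test_action_reaction(self, default_trial):
        calib = hx.calibrate_trial(default_trial).with_alpha(0.7)
        dec = hx.residual_hip_moment(default_trial, calib)
        assert np.allclose(dec.applied["left"] + dec.applied["right"], 0.0, atol=1e-12)

    def test_labels_change_only_where_torque_acts(self, default_trial):
        calib = hx.calibrate_trial(default_trial)
        dec0 = hx.residual_hip_moment(default_trial, calib.with_alpha(0.0))
        dec1 = hx.residual_hip_moment(default_trial, calib.with_alpha(0.5))
        for side in ("left", "right"):
            changed = dec0.region[side] != dec1.region[side]
            assert np.all(dec1.applied[side][changed] != 0.0)


class TestAlphaOptimum:
    def test_calibrated_spring_is_optimal_at_one(self):
        for seed, trial in enumerate(hx.make_cohort(5, seed=17)):
            calib = hx.calibrate_trial(trial)
            assert hx.alpha_optimum_for_squared_moment(trial, calib) == pytest.approx(
                1.0, abs=1e-9
            )

    def test_grid_search_confirms_unity(self, default_trial):
        calib = hx.calibrate_trial(default_trial)
        alphas = np.round(np.arange(0.0, 1.51, 0.1), 10)
        js = [hx.squared_moment_integral(default_trial, calib, a) for a in alphas]
        assert alphas[int(np.argmin(js))] == pytest.approx(1.0)

    def test_degenerate_spring_raises(self, grid):
        t, s, c = grid
        tr = _simple_trial(s, np.zeros_like(s), -c, c)  # moment orthogonal to dtheta
        calib = hx.calibrate_trial(tr)
        assert calib.k_inv == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(DegenerateCalibrationError):
            hx.alpha_optimum_for_squared_moment(tr, calib)

    def test_j_is_convex_quadratic_with_vertex_at_one(self, default_trial):
        calib = hx.calibrate_trial(default_trial)
        J = lambda a: hx.squared_moment_integral(default_trial, calib, a)
        # symmetric around the vertex and positive curvature
        assert J(1.3) == pytest.approx(J(0.7), rel=1e-9)
        assert J(0.0) + J(2.0) - 2 * J(1.0) > 0

    def test_monotone_improvement_then_degradation(self, default_trial):
        calib = hx.calibrate_trial(default_trial)
        alphas = np.linspace(0, 1.5, 16)
        js = np.array([hx.squared_moment_integral(default_trial, calib, a) for a in alphas])
        upward = alphas <= 1.0
        assert np.all(np.diff(js[upward]) <= 0)
        assert np.all(np.diff(js[~upward]) >= 0)
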