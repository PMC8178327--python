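import numpy as np
import pandas as pd
import pytest

import hipexo as hx
from hipexo.sweep_stats import (
    DEFAULT_ALPHA_GRID,
    SweepResult,
    _holm,
    fit_quadratic,
    linreg_jackknife,
    paired_t_holm,
    pearson,
    rs_prediction_curves,
    run_sweep,
)


class TestFitQuadratic:
    def test_exact_parabola_recovered(self):
        x = DEFAULT_ALPHA_GRID
        fit = fit_quadratic(x, (x - 0.6) ** 2)
        assert fit.a == pytest.approx(1.0, abs=1e-10)
        assert fit.argmin == pytest.approx(0.6, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.convex

    def test_constant_series_degenerates(self):
        fit = fit_quadratic(np.arange(5.0), np.full(5, 3.0))
        assert fit.a == pytest.approx(0.0, abs=1e-12)
        assert fit.b == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == 0.0
        assert not fit.convex and fit.argmin is None

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_quadratic([0.0, 1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            fit_quadratic([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_argmin_recovery_under_noise(self):
        # distribution check: the fitted vertex is unbiased around 0.6
        rng = np.random.default_rng(0)
        x = DEFAULT_ALPHA_GRID
        argmins = []
        for _ in range(200):
            y = (x - 0.6) ** 2 + rng.normal(0, 0.05, x.size)
            argmins.append(fit_quadratic(x, y).argmin)
        sem = np.std(argmins, ddof=1) / np.sqrt(len(argmins))
        assert abs(np.mean(argmins) - 0.6) < 2 * sem + 1e-3


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_textbook_value(self):
        r, p = pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)
        assert 0 < p < 1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [1.0, 2.0])


class TestJackknife:
    def test_collinear_points_have_no_outliers(self):
        x = np.arange(8.0)
        reg = linreg_jackknife(x, 3 * x - 1)
        assert not reg.outliers.any()
        assert reg.r2 == pytest.approx(1.0)
        assert reg.slope == pytest.approx(3.0)

    def test_gross_outlier_flagged_alone(self):
        x = np.arange(10.0)
        y = 2 * x + 1 + np.random.default_rng(4).normal(0, 0.05, 10)
        y[6] += 25.0
        reg = linreg_jackknife(x, y)
        assert list(np.nonzero(reg.outliers)[0]) == [6]
        assert reg.r2_refit > reg.r2

    def test_flagging_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 10, 12)
        y = 1.5 * x + rng.normal(0, 1.0, 12)
        base = linreg_jackknife(x, y).outliers
        scaled = linreg_jackknife(100 * x - 3, 0.01 * y + 7).outliers
        assert np.array_equal(base, scaled)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            linreg_jackknife([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            linreg_jackknife([2, 2, 2, 2], [1, 2, 3, 4])


class TestPairedTHolm:
    def test_holm_step_down_example(self):
        adj = _holm(np.array([0.01, 0.02, 0.04]))
        assert np.allclose(adj, [0.03, 0.04, 0.04])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 15)
        assert np.all(_holm(p) >= p)
        assert np.all(_holm(p) <= 1.0)

    def test_identical_conditions_give_unit_p(self):
        M = np.tile(np.arange(5.0)[:, None], (1, 3))
        with pytest.warns(UserWarning):
            out = paired_t_holm(M)
        assert np.all(out["p_raw"] == 1.0)
        assert np.all(out["p_holm"] == 1.0)

    def test_pairwise_layout(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(6, 4))
        out = paired_t_holm(M, labels=list("abcd"))
        assert len(out) == 6  # 4 choose 2
        assert set(out.columns) == {"cond_a", "cond_b", "p_raw", "p_holm"}

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            paired_t_holm(np.ones((1, 3)))
        with pytest.raises(ValueError):
            paired_t_holm(np.ones(5))


def _tiny_sweep(n=2, alphas=(0.0, 0.5)):
    cohort = hx.make_cohort(n, seed=6)
    return run_sweep(cohort, alphas=np.array(alphas))


class TestRunSweep:
    def test_default_grid_has_sixteen_coefficients(self, default_sweep):
        assert default_sweep.alphas.size == 16
        assert default_sweep.table.shape[0] == 7 * 16
        assert not default_sweep.table.isna().any().any()

    def test_single_point_grid_is_baseline(self):
        sw = _tiny_sweep(alphas=(0.0,))
        assert sw.alpha_star == 0.0
        assert sw.table.shape[0] == 2
        assert sw.quadratic_fits == {}

    def test_rerun_is_identical(self):
        a = _tiny_sweep()
        b = _tiny_sweep()
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_baseline_reduction_is_exactly_zero(self, default_sweep):
        assert np.all(default_sweep.reductions(0.0).to_numpy() == 0.0)

    def test_optima_lie_on_grid(self, default_sweep):
        assert default_sweep.alpha_star in default_sweep.alphas
        assert default_sweep.alpha_hash in default_sweep.alphas

    def test_quadratic_fit_argmin_close_to_grid_argmin(self, default_sweep):
        fit = default_sweep.quadratic_fits["fatigue_all"]
        assert fit.convex
        assert abs(fit.argmin - default_sweep.alpha_hash) <= 0.1 + 1e-9

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            run_sweep([])
        with pytest.raises(ValueError):
            run_sweep(hx.make_cohort(1, seed=0), alphas=np.array([0.5, 0.1]))


def _synthetic_sweep_linear_in_rs(n_subj=6, alpha=0.5, slope=0.04, intercept=0.01):
    """A sweep table whose reduction is an exact linear function of RS."""
    rs = np.linspace(2.0, 6.0, n_subj)
    rows = []
    for i, r in enumerate(rs):
        rate0 = 10.0
        red = intercept + slope * r
        for a, rate in ((0.0, rate0), (alpha, rate0 * (1 - red))):
            rows.append(
                {"subject": f"S{i}", "alpha": a, "metabolic_rate": rate, "rs": r}
            )
    return SweepResult(
        alphas=np.array([0.0, alpha]),
        table=pd.DataFrame(rows),
        quadratic_fits={},
        alpha_star=alpha,
        alpha_hash=alpha,
        correlations={},
        rs_regressions=pd.DataFrame(),
        kinv={},
    )


class TestRSPrediction:
    def test_exact_linear_construction_gives_unit_r2(self):
        sw = _synthetic_sweep_linear_in_rs()
        curves = rs_prediction_curves(sw)
        assert curves["r2"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert curves["slope"].iloc[0] == pytest.approx(0.04, abs=1e-12)

    def test_needs_at_least_four_subjects(self):
        sw = _synthetic_sweep_linear_in_rs(n_subj=3)
        with pytest.raises(ValueError):
            rs_prediction_curves(sw)

    def test_default_cohort_slopes_positive(self, default_sweep):
        curves = rs_prediction_curves(default_sweep)
        assert np.all(curves["slope"] > 0)
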