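"""Spring-coefficient sweep orchestration and its statistical surface.

For each subject the spring stiffness is calibrated once on the baseline
stride, then every spring coefficient ``alpha`` on the grid (default 0 to
1.5 in steps of 0.1) is evaluated end to end: torque decomposition, muscle
redundancy resolution, metabolic and fatigue indices.  On top of the
per-(subject, alpha) table the module provides the analysis layer:

* quadratic dose-response fits of the cohort-mean metabolic rate and
  fatigue against alpha, with the grid optima ``alpha_star`` (metabolic)
  and ``alpha_hash`` (fatigue);
* Pearson correlation between the two-muscle (mono-articular hip pair)
  fatigue and the all-muscle fatigue / metabolic rate across the grid —
  the observable behind adapting stiffness from two EMG channels only;
* per-alpha ordinary least-squares regressions of the fractional metabolic
  reduction on the kinematic RS index, with jackknife
  (externally-studentized-residual) outlier flagging;
* pairwise paired t-tests across alpha conditions with Holm-Bonferroni
  step-down correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .energetics import EnergeticsConfig, metabolic_rate
from .exo_spring import calibrate_trial, residual_hip_moment
from .gait_synth import JOINTS, GaitTrial
from .indices import (
    IndexReport,
    average_abs_moment,
    average_force,
    fatigue_all,
    fatigue_mono,
    kinematic_indices,
)
from .muscle_model import MuscleModelSpec, default_model
from .static_opt import solve_trial

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "QuadraticFit",
    "JackknifeRegression",
    "SweepResult",
    "run_sweep",
    "fit_quadratic",
    "pearson",
    "linreg_jackknife",
    "paired_t_holm",
    "rs_prediction_curves",
]

DEFAULT_ALPHA_GRID = np.round(np.arange(0.0, 1.5001, 0.1), 10)


@dataclass(frozen=True)
class QuadraticFit:
    """Least-squares parabola ``y = a x^2 + b x + c``."""

    a: float
    b: float
    c: float
    r2: float
    argmin: float | None   # -b / 2a when convex, else None
    convex: bool

    def __call__(self, x):
        return self.a * np.asarray(x) ** 2 + self.b * np.asarray(x) + self.c


@dataclass(frozen=True)
class JackknifeRegression:
    slope: float
    intercept: float
    r2: float
    outliers: np.ndarray          # boolean mask
    slope_refit: float
    intercept_refit: float
    r2_refit: float


@dataclass
class SweepResult:
    alphas: np.ndarray
    table: pd.DataFrame                 # one row per (subject, alpha)
    quadratic_fits: dict                # index name -> QuadraticFit
    alpha_star: float
    alpha_hash: float
    correlations: dict                  # pair name -> (r, p)
    rs_regressions: pd.DataFrame        # per alpha > 0
    kinv: dict                          # subject -> calibrated stiffness

    def mean_curve(self, column: str) -> np.ndarray:
        g = self.table.groupby("alpha")[column].mean()
        return g.reindex(self.alphas).to_numpy()

    def reductions(self, alpha: float) -> pd.Series:
        """Per-subject fractional metabolic reduction at one alpha."""
        piv = self.table.pivot(index="subject", columns="alpha", values="metabolic_rate")
        return (piv[0.0] - piv[alpha]) / piv[0.0]


def _subject_report(trial, spec, energy_cfg, calib, alpha, sign_tolerance):
    dec = residual_hip_moment(trial, calib.with_alpha(alpha), sign_tolerance=sign_tolerance)
    sol = solve_trial(trial, dec, spec)
    t, T, m = trial.time, trial.stride_period, trial.mass
    rate = metabolic_rate(trial, sol, energy_cfg, spec=spec)
    avg_mom = {}
    for joint in JOINTS:
        per_side = []
        for side in ("left", "right"):
            tau = dec.tau_bio[side] if joint == "hip" else trial.moments[(joint, side)]
            per_side.append(average_abs_moment(tau, t, T, m))
        avg_mom[joint] = float(np.mean(per_side))
    avg_f = {
        key: average_force(sol.forces[:, i], t, T, m)
        for i, key in enumerate(sol.muscle_keys)
    }
    rm, sm, rs = kinematic_indices(trial)
    return IndexReport(
        subject_id=trial.subject_id,
        alpha=float(alpha),
        metabolic_rate=rate,
        avg_abs_moment=avg_mom,
        avg_force=avg_f,
        fatigue_all=fatigue_all(sol, spec, t, T),
        fatigue_mono=fatigue_mono(sol, spec, t, T),
        rm=rm,
        sm=sm,
        rs=rs,
    )


def _report_row(rep: IndexReport) -> dict:
    row = {
        "subject": rep.subject_id,
        "alpha": rep.alpha,
        "metabolic_rate": rep.metabolic_rate,
        "fatigue_all": rep.fatigue_all,
        "fatigue_mono": rep.fatigue_mono,
        "rm": rep.rm,
        "sm": rep.sm,
        "rs": rep.rs,
    }
    row.update({f"avg_abs_moment_{j}": v for j, v in rep.avg_abs_moment.items()})
    row.update({f"avg_force_{k}": v for k, v in rep.avg_force.items()})
    return row


def run_sweep(
    cohort: list,
    spec: MuscleModelSpec | None = None,
    energetics_config: EnergeticsConfig | None = None,
    alphas: np.ndarray | None = None,
    sign_tolerance: float = 0.5,
    jackknife_level: float = 0.05,
) -> SweepResult:
    """Evaluate the full pipeline on a cohort over a spring-coefficient grid."""
    if not cohort:
        raise ValueError("cohort must be non-empty")
    alphas = DEFAULT_ALPHA_GRID if alphas is None else np.asarray(alphas, dtype=float)
    if alphas.size == 0:
        raise ValueError("alpha grid must be non-empty")
    if np.any(np.diff(alphas) <= 0):
        raise ValueError("alpha grid must be sorted and unique")
    spec = spec or default_model()
    energy_cfg = energetics_config or EnergeticsConfig()

    rows, kinv = [], {}
    for trial in cohort:
        calib = calibrate_trial(trial)
        kinv[trial.subject_id] = calib.k_inv
        for alpha in alphas:
            try:
                rep = _subject_report(trial, spec, energy_cfg, calib, alpha, sign_tolerance)
            except Exception as exc:
                raise RuntimeError(
                    f"sweep failed for subject {trial.subject_id} at alpha={alpha}: {exc}"
                ) from exc
            rows.append(_report_row(rep))
    table = pd.DataFrame(rows)

    mean_rate = table.groupby("alpha")["metabolic_rate"].mean().reindex(alphas)
    mean_fat_all = table.groupby("alpha")["fatigue_all"].mean().reindex(alphas)
    mean_fat_mono = table.groupby("alpha")["fatigue_mono"].mean().reindex(alphas)

    fits, correlations = {}, {}
    if alphas.size >= 3:
        fits["metabolic_rate"] = fit_quadratic(alphas, mean_rate.to_numpy())
        fits["fatigue_all"] = fit_quadratic(alphas, mean_fat_all.to_numpy())
        fits["fatigue_mono"] = fit_quadratic(alphas, mean_fat_mono.to_numpy())
        correlations["fatigue_mono_vs_all"] = pearson(
            mean_fat_mono.to_numpy(), mean_fat_all.to_numpy()
        )
        correlations["fatigue_mono_vs_metabolic"] = pearson(
            mean_fat_mono.to_numpy(), mean_rate.to_numpy()
        )
    alpha_star = float(alphas[int(np.argmin(mean_rate.to_numpy()))])
    alpha_hash = float(alphas[int(np.argmin(mean_fat_all.to_numpy()))])

    result = SweepResult(
        alphas=alphas,
        table=table,
        quadratic_fits=fits,
        alpha_star=alpha_star,
        alpha_hash=alpha_hash,
        correlations=correlations,
        rs_regressions=pd.DataFrame(),
        kinv=kinv,
    )
    n_subjects = table["subject"].nunique()
    if n_subjects >= 4 and 0.0 in alphas and alphas.size > 1:
        result.rs_regressions = _rs_regression_table(result, jackknife_level)
    return result


def _rs_regression_table(sweep: SweepResult, level: float) -> pd.DataFrame:
    rs = sweep.table.pivot(index="subject", columns="alpha", values="rs").iloc[:, 0]
    recs = []
    for alpha in sweep.alphas:
        if alpha == 0.0:
            continue
        red = sweep.reductions(alpha).reindex(rs.index)
        reg = linreg_jackknife(rs.to_numpy(), red.to_numpy(), level=level)
        recs.append(
            {
                "alpha": alpha,
                "slope": reg.slope,
                "intercept": reg.intercept,
                "r2": reg.r2,
                "n_outliers": int(reg.outliers.sum()),
                "outliers": ";".join(rs.index[reg.outliers]),
                "slope_refit": reg.slope_refit,
                "r2_refit": reg.r2_refit,
            }
        )
    return pd.DataFrame(recs)


def fit_quadratic(x, y) -> QuadraticFit:
    """Least-squares second-order polynomial with R^2 and convex argmin."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or np.unique(x).size < 3:
        raise ValueError("quadratic fit needs at least 3 distinct x values")
    coeffs = np.polyfit(x, y, 2)
    a, b, c = (float(v) for v in coeffs)
    resid = y - np.polyval(coeffs, x)
    sstot = float(np.sum((y - y.mean()) ** 2))
    # Zero-variance y: define R^2 = 0 (flagged by convexity=False when a=0)
    r2 = 0.0 if sstot == 0 else 1.0 - float(np.sum(resid**2)) / sstot
    # Curvature at rounding level (e.g. a constant series) is not convex.
    convex = a > 1e-12 * max(1.0, float(np.max(np.abs(y))))
    return QuadraticFit(a, b, c, r2, argmin=(-b / (2 * a) if convex else None), convex=convex)


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("pearson needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def linreg_jackknife(x, y, level: float = 0.05) -> JackknifeRegression:
    """OLS with jackknife outlier flagging.

    A point is an outlier when its externally studentized (leave-one-out)
    residual exceeds the two-sided t critical value at ``level`` with
    ``n - 3`` degrees of freedom.  The fit is reported with and without the
    flagged points.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("jackknife regression needs n >= 4")
    if np.ptp(x) == 0:
        raise ValueError("x is degenerate (zero variance)")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    if fit.ssr <= 1e-20 * max(1.0, float(np.sum(y**2))):
        # numerically exact fit: studentization is 0/0 noise, no outliers
        outliers = np.zeros(n, dtype=bool)
    else:
        infl = fit.get_influence()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # exact LOO fits -> 0/0
            student = np.nan_to_num(infl.resid_studentized_external, nan=0.0)
        crit = stats.t.ppf(1.0 - level / 2.0, n - 3)
        outliers = np.abs(student) > crit
    keep = ~outliers
    if keep.sum() >= 2 and np.ptp(x[keep]) > 0:
        refit = sm.OLS(y[keep], sm.add_constant(x[keep])).fit()
        slope_refit, intercept_refit = float(refit.params[1]), float(refit.params[0])
        r2_refit = float(refit.rsquared)
    else:
        slope_refit, intercept_refit, r2_refit = float(fit.params[1]), float(fit.params[0]), float(fit.rsquared)
    return JackknifeRegression(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r2=float(fit.rsquared),
        outliers=outliers,
        slope_refit=slope_refit,
        intercept_refit=intercept_refit,
        r2_refit=r2_refit,
    )


def paired_t_holm(condition_matrix: np.ndarray, labels=None) -> pd.DataFrame:
    """All pairwise paired two-sided t-tests with Holm-Bonferroni adjustment.

    ``condition_matrix`` is subjects x conditions.  Zero-variance
    differences (identical columns) yield p = 1 with a warning.  Adjusted p
    values are the Holm step-down values with monotonicity enforced and are
    never below the raw p.
    """
    M = np.asarray(condition_matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    labels = list(labels) if labels is not None else list(range(M.shape[1]))
    pairs, raw = [], []
    for i, j in itertools.combinations(range(M.shape[1]), 2):
        d = M[:, i] - M[:, j]
        if np.ptp(d) == 0:
            warnings.warn(
                f"conditions {labels[i]} and {labels[j]} have zero-variance differences; p set to 1",
                UserWarning,
                stacklevel=2,
            )
            p = 1.0
        else:
            p = float(stats.ttest_rel(M[:, i], M[:, j]).pvalue)
        pairs.append((labels[i], labels[j]))
        raw.append(p)
    raw = np.asarray(raw)
    adjusted = _holm(raw)
    return pd.DataFrame(
        {
            "cond_a": [p[0] for p in pairs],
            "cond_b": [p[1] for p in pairs],
            "p_raw": raw,
            "p_holm": adjusted,
        }
    )


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment with running-max monotonicity."""
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def rs_prediction_curves(sweep: SweepResult) -> pd.DataFrame:
    """Per-alpha slope and R^2 of the reduction-vs-RS regression.

    Reduction is each subject's fractional drop from their own baseline
    rate, ``(rate(0) - rate(alpha)) / rate(0)``, regressed on the baseline
    RS index at each nonzero alpha.
    """
    n_subjects = sweep.table["subject"].nunique()
    if n_subjects < 4:
        raise ValueError("RS prediction curves need >= 4 subjects")
    if 0.0 not in sweep.alphas:
        raise ValueError("alpha grid must contain 0 (the baseline condition)")
    if not len(sweep.rs_regressions):
        sweep.rs_regressions = _rs_regression_table(sweep, level=0.05)
    return sweep.rs_regressions[["alpha", "slope", "r2"]].copy()
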