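# hipexo

Simulation-based assessment of a **passive hip-coupling exoskeleton** for
running gait. A torsional spring couples the two hips and applies a torque
proportional to the instantaneous left–right hip-angle difference,

```
dtheta(t) = q_hip,left(t) - q_hip,right(t)
tau_a(t)  = alpha * K_inv * dtheta(t)
```

with action–reaction between the sides. The package answers, on a
synthetic running cohort or on user-supplied bilateral joint angle/moment
time series, the questions a device designer asks:

* **How stiff should the spring be?** `K_inv` is calibrated per subject as
  the least-squares minimiser of the stride-integrated squared residual
  biological hip moment (closed form); the dimensionless spring
  coefficient `alpha` then sweeps around it (`alpha = 0`: no assistance;
  `alpha = 1`: full least-squares compensation, provably the
  residual-moment optimum).
* **What do the muscles do?** Per frame, muscle forces resolve the
  redundancy problem `min Σ(f_i/ω_i)² + Σ(r_j/ω_j)² + Σ(R_k/ω_k)²`
  subject to joint-moment equality constraints and `0 ≤ f_i ≤ f_iso,i`,
  over a reduced 9-muscle-per-leg sagittal model (Psoas, Gluteus Maximus,
  Rectus Femoris, Semimembranosus, Vastus Lateralis, Biceps Femoris short
  head, Gastrocnemius Medialis, Tibialis Anterior, Soleus) with penalized
  reserve actuators. The convex QP is solved to certified KKT optimality
  at every sample.
* **What does it cost?** A pluggable metabolic proxy (activation-squared
  heat + positive mechanical work / efficiency) gives a normalized rate in
  W/kg; effort is tracked by the fatigue index — the stride-average of the
  summed squared normalized muscle forces — for all muscles and for the
  antagonistic mono-articular hip pair (Psoas + Gluteus Maximus) alone.
* **Who benefits?** The kinematic indices
  `RM = |A - B|`, `SM = |A + B|⁻¹`, `RS = RM × SM`
  (A = stride-max left-hip angle, B = stride-min right-hip angle) predict
  each subject's metabolic reduction; the sweep layer fits quadratic
  dose-response curves, correlates two-muscle against all-muscle fatigue,
  and regresses reduction on RS per coefficient with jackknife outlier
  flagging and Holm-corrected paired t-tests.

The bundled generator produces stride-periodic cohorts from finite Fourier
series — exactly periodic, analytically differentiable, with controllable
hip range, left/right symmetry, antiphase lag and biphasic hip moments —
so the full analysis runs without any motion-capture data. See
`docs/methods.md` for model details, defaults and declared limitations.

## Worked example

```python
import hipexo as hx

trial = hx.make_subject(seed=1)           # one default synthetic stride
calib = hx.calibrate_trial(trial)         # least-squares spring stiffness
print(f"K_inv = {calib.k_inv:.4f} N*m/rad")

rm, sm, rs = hx.kinematic_indices(trial)
print(f"RM = {rm:.4f} rad, SM = {sm:.4f} 1/rad, RS = {rs:.4f}")

spec = hx.default_model()
base = hx.solve_trial(trial, None, spec)  # no-device muscle forces
dec = hx.residual_hip_moment(trial, calib.with_alpha(0.6))
assisted = hx.solve_trial(trial, dec, spec)

r0 = hx.metabolic_rate(trial, base, spec=spec)
r6 = hx.metabolic_rate(trial, assisted, spec=spec)
print(f"metabolic rate: {r0:.4f} -> {r6:.4f} W/kg "
      f"({100 * (1 - r6 / r0):.2f}% reduction at alpha = 0.6)")
```

prints

```
K_inv = 60.5942 N*m/rad
RM = 0.8700 rad, SM = 5.8817 1/rad, RS = 5.1169
metabolic rate: 19.4801 -> 13.7910 W/kg (29.21% reduction at alpha = 0.6)
```

The calibrated stiffness is ~60 N·m/rad for this subject; at spring
coefficient 0.6 the hip muscles shed a large share of their load and the
proxy metabolic rate drops accordingly. (Reductions under the proxy are
larger than physiological ones — there is no basal rate; see the methods
note.) The full sweep is one call:

```python
cohort = hx.make_cohort(7, seed=42)
sweep = hx.run_sweep(cohort)              # 16 coefficients, 0.0 .. 1.5
print(sweep.alpha_star,                   # grid optimum of the mean metabolic rate
      sweep.correlations["fatigue_mono_vs_all"])  # two- vs all-muscle fatigue
```

On the default cohort the mean metabolic rate is almost exactly quadratic
in the coefficient (R² > 0.999) with its grid optimum at `alpha* = 1.1`,
and two-muscle fatigue tracks all-muscle fatigue with Pearson r > 0.99
across the grid — the observable that lets stiffness be adapted from two
EMG channels.

From the shell, the same pipeline is:

```bash
hipexo run --out results_dir          # generate -> calibrate -> sweep -> CSVs
hipexo generate --n 7 --seed 42 --out cohort/
hipexo calibrate cohort/S01.sto
hipexo indices cohort/S01.sto
hipexo model show
```

`hipexo run` writes the cohort as OpenSim-style `.sto` files plus
`indices.csv`, `sweep_summary.csv`, `fits.csv`, `correlations.csv`,
`regressions.csv` and a `run_log.json` recording seed, config hash and
version; identical configs produce byte-identical outputs.

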