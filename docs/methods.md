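# Methods

## The model in brief

A passive exoskeleton couples the two hips with a torsional spring whose
torque is proportional to the instantaneous difference between left and
right hip flexion angles,

    dtheta(t) = q_hip,left(t) - q_hip,right(t),
    tau_a(t)  = alpha * K_inv * dtheta(t),

applied with opposite signs to the two hips (action–reaction; by default
`+tau_a` on the right). Because the torque is a pure function of the
kinematics, the device can be assessed on a fixed gait: the kinematics are
assumed unchanged by assistance, and the muscles must produce the
*residual* biological moment `tau_bio = tau_baseline - tau_applied` at the
hip while knee and ankle demands are untouched.

`K_inv` is the stiffness that minimises the stride integral of the squared
residual hip moment over both sides,

    K_inv = ∫ (tau_r - tau_l) dtheta dt / (2 ∫ dtheta² dt),

a scalar least-squares projection with a closed form. The dimensionless
spring coefficient `alpha` rescales it; by construction the residual-moment
objective `J(alpha)` is a convex quadratic with its minimum exactly at
`alpha = 1`, which the test suite asserts to 1e-9. All stride integrals use
trapezoidal quadrature with an explicit wrap segment from the last sample
back to the (periodic) first, so full-period harmonic orthogonality holds
exactly on the endpoint-free uniform grid.

Calibration is joint over both hips because the physical spring is a single
element; for antiphase-symmetric gait this coincides with single-sided
calibration. Whether to calibrate per subject or per cohort is genuinely
open; per-subject calibration is used throughout, which pins every
subject's hip-moment optimum at `alpha = 1` and makes coefficients
comparable across subjects.

## Muscle redundancy resolution

Per time frame, muscle forces `f`, joint reserve torques `r` and optional
residual torques `R` minimise

    J(f, r, R) = Σ (f_i/ω_i)² + Σ (r_j/ω_j)² + Σ (R_k/ω_k)²

subject to `A f + r (+R) = tau_target` per joint and `0 ≤ f_i ≤ f_iso,i`.
With the default `ω_i = f_iso,i` the muscle term is the summed squared
normalized force — the classic effort cost. Reserve weights default to
1 N·m, small against the 50–90 N·m moment scale, so reserves are expensive
feasibility slacks (observed peak reserve usage on the default cohort is
~0.02 N·m). Residual slacks are off by default: the reduced model has no
pelvis-ground joint; a flag enables them as per-joint slacks to mirror the
full-model structure.

This is per-frame static optimization; a tracking controller would add
smoothness across frames but needs forward dynamics the reduced model does
not carry. The kinematics being fixed by assumption, the per-frame problem
is the stationary limit of such a controller.

Solver: the Hessian is diagonal and the only coupling is the joint-moment
equalities, so the dual in the joint multipliers λ is strictly concave and
piecewise quadratic — the free reserves contribute `ω_r²/2` to the dual
Hessian diagonal, so it is uniformly positive definite. A semismooth Newton
iteration with Armijo backtracking on the dual objective solves each frame
(interior stationarity is exact by construction; the verified KKT residual
is bounded by the constraint residual, tolerance 1e-10 relative, hard
ceiling 1e-8). Consecutive frames warm-start from the previous multipliers.
The solution of the strictly convex QP is unique, so repeat runs are
bitwise identical. An exhaustive active-set enumeration oracle in the test
suite independently certifies global optimality on randomized instances.

### Reduced muscle set

Nine muscle branches per leg (Psoas, Gluteus Maximus, Rectus Femoris,
Semimembranosus, Vastus Lateralis, Biceps Femoris short head —
modelled knee-only, Gastrocnemius Medialis, Tibialis Anterior, Soleus) with
constant signed moment arms on hip/knee/ankle, flexion-positive (ankle
dorsiflexion positive). This is an explicit reduction from full-body
musculoskeletal models: it preserves the named muscles, their mono-/
bi-articular pattern and antagonism at every joint, not anatomical
geometry. Moment arms and isometric forces live in a bundled YAML
(`data/default_muscles.yaml`) and are literature-plausible configuration,
not subject-specific claims; polynomial angle-dependent arms are supported
but off by default.

## Metabolic proxy

Full muscle-energetics models partition heat by fibre state and need
Hill-type internal variables absent here. The pluggable proxy used instead
is

    P_i = c_h · f_iso,i · a_i²  +  max(0, f_i · Σ_j A[j,i] qdot_j) / η,

activation heat quadratic in normalized force `a_i = f_i/f_iso,i`
(`c_h = 0.5 W/N` default) plus positive mechanical work converted at the
classic efficiency `η = 0.25`. Negative (eccentric) work is costed at zero.
The whole-body rate is the stride-averaged summed power per kilogram of
body mass. Consequences to keep in mind: the proxy inherits the quadratic
structure of the effort cost, so the metabolic optimum on synthetic data
falls near the hip-moment optimum (`alpha ≈ 1.0–1.1`), not at the moderate
coefficients reported for physiological energetics models on real gait;
no basal rate is included, so *fractional* reductions are larger than
physiological ones. Dose-response shape, correlation structure and index
regressions are the meaningful outputs, not absolute watts.

## Synthetic gait generator

All channels are finite Fourier series (≤ 5 harmonics) in stride phase:
periodicity is exact by construction, velocities are analytic derivatives,
and coefficient-space noise preserves both. The hip waveform is scaled and
shifted so its extrema hit `hip_flexion_peak` / `hip_extension_min`
exactly; the left side is the right side phase-shifted by `phase_lag`
strides (0.5 = antiphase) plus a constant `symmetry_offset`, so the
kinematic indices are directly controllable:

    A = max q_l,  B = min q_r,
    RM = |A - B|,  SM = |A + B|⁻¹,  RS = RM·SM.

SM is computed in rad⁻¹; it diverges for a perfectly symmetric gait and is
reported as an error, never capped. Baseline moments are biphasic at the
hip — the first harmonic deliberately anti-aligned with the hip angle up to
a misalignment of 0.35 rad, so the spring is useful but imperfect —
predominantly extensor at the knee and plantarflexor at the ankle, with
amplitudes giving ~1 N·m/kg peak hip moment at default mass.

Grid and anthropometry defaults: N = 200 samples/stride, T = 0.7 s,
mass 70.9 kg (cohort mean of the running dataset the study design targets),
cohort size 7. Cohort heterogeneity (uniform ranges): hip extrema spanning
ranges of motion ~0.76–1.1 rad, symmetry offsets 0 to ~11°, phase lag
0.49–0.51, mass 63.9–77.9 kg, stride period 0.65–0.75 s, hip-moment
amplitude 55–75 N·m. The symmetry offset is deliberately the dominant
inter-subject axis: it feeds a DC component into `dtheta` that is nearly
orthogonal to the biphasic hip moment, so spring benefit falls with
asymmetry and rises with range — the structure the RS regression assumes.
Steady running is tightly antiphase, so phase-lag jitter (which would add
RS-independent variance) is kept small.

What the generator does **not** emulate: measured joint-angle waveforms
(none are published for the target dataset), ground-reaction forces,
stance/swing asymmetries of the moment profile, speed variation,
within-subject stride-to-stride variability, and frontal-plane motion.
Passing tests therefore demonstrate the *machinery* and the *qualitative
structure* (quadratic dose-response, fatigue correlation, positive
RS-reduction slopes), not quantitative fidelity to any experimental
cohort.

## Statistics layer

* Quadratic dose-response fits by ordinary least squares; R² by the usual
  variance decomposition with R² ≡ 0 for zero-variance targets; a fit is
  "convex" only if the curvature exceeds rounding level relative to the
  data scale. Grid optima are reported alongside fitted vertices; on the
  default cohort they agree within one grid step.
* Pairwise paired two-sided t-tests across coefficients with Holm
  step-down adjustment (running-max monotonicity, capped at 1);
  zero-variance differences give p = 1 with a warning.
* Reduction-vs-RS regressions per coefficient: reduction is each subject's
  fractional drop from their own baseline rate (exactly 0 at `alpha = 0`).
  Outliers are flagged by externally studentized (leave-one-out) residuals
  against the two-sided t critical value at level 0.05 with n−3 degrees of
  freedom — a declared convention, as the criterion's reference
  distribution is not standardised; numerically exact fits are declared
  outlier-free. Fits are reported with and without flagged points.
* The fatigue correlation check compares cohort-mean two-muscle
  (Psoas + Gluteus Maximus) fatigue against all-muscle fatigue across the
  16-point coefficient grid.

A mixed-model ANOVA with random subject effects is deliberately not
implemented: it is off-the-shelf machinery, and the paired-t/Holm surface
plus the quadratic fixed-effect fits carry the same comparisons here.

## Numerical choices and degenerate inputs

| Quantity | Default | Note |
|---|---|---|
| QP constraint tolerance | 1e-10 relative | dual residual, per frame |
| QP KKT ceiling | 1e-8 | hard error above |
| Spring degeneracy | `dtheta ≡ 0` → error; `|K_inv| < 1e-9` N·m/rad → error | spring cannot act / orthogonal moment |
| SM guard | `|A+B| ≤ 1e-6` rad → error | never capped |
| Region labels | neutral when `|tau_baseline| < 0.5` N·m or `tau_a = 0` | avoids chatter at zero crossings |
| Linear spring range | warn above 30° deflection (opt-in) | torque stays linear |
| Periodicity tolerance | 1e-6 rad | exact (≤1e-12) for generated trials |

## Problem sizes

The default study conditions — 7 subjects × 16 coefficients × 200 frames ×
24 actuators — solve in a few seconds on one core; the full test suite
(including the randomized oracle comparisons and the complete default
sweep) runs in well under a minute.

## Known limitations

* 18 muscles / 6 moment channels cannot reproduce per-muscle force
  magnitudes of a full-body model; only orderings and trends are asserted
  (e.g. ankle muscles respond less than hip muscles to hip assistance).
* The metabolic proxy's optimum tracks the effort optimum by construction;
  divergence between metabolic and fatigue optima seen with richer
  energetics models will not appear here.
* Constant moment arms ignore configuration dependence; the polynomial
  hook exists but ships disabled.
* Single-stride trials only; multi-stride inputs should be split and
  averaged per stride before indexing.
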