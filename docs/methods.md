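# Methods

This note documents the estimators, the evaluation protocol and the
synthetic-data model implemented in `fsrcop`, together with the numerical
choices and known limitations. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate frame and units

All positions are in millimetres in the insole frame: the x-axis is the
tangent to the bottom (posterior) edge of the insole and measures
medial-lateral (ML) position; the y-axis is the tangent to the left edge
and measures anterior-posterior (AP) position; the origin is their
intersection. Forces are in newtons, sampled at 50 Hz by default. Left and
right feet are treated as independent subject-feet with their own layouts
and their own fitted models; mirroring a layout for the contralateral foot
is the caller's responsibility.

The shipped 12-sensor layout covers the great toe, lesser toes, the five
metatarsal heads, the arch/midfoot and the heel of a US-9 insole
(100 x 280 mm bounding box). Its numeric coordinates are a configuration
default, not a measurement; every estimator takes the layout as an
explicit argument so alternative layouts are first-class.

## Estimators

**Weighted mean.** Per frame, the force-weighted average of the sensor
coordinates. It is scale-invariant in the forces, translation-equivariant
in the coordinates, and always lies in the convex hull of the loaded
sensors. Frames with zero total force have no defined COP and raise an
error (the evaluation layer can optionally drop them with a logged count).

**Fitted model.** Per axis, a linear form in the sensor forces whose
coefficients minimise the squared error against a paired reference
trajectory, fitted per subject-foot on all tasks pooled. Two variants:

- `linear`: predictors are the 12 forces plus their sum (13 columns).
  The 13th column is by construction the exact row sum of the first 12,
  so the Gram matrix is singular. The fit is the minimum-norm
  least-squares solution via SVD with a relative singular-value cutoff of
  1e-10 (`numpy.linalg.lstsq`). The one-dimensional null space — add
  delta to the total-force coefficient, subtract delta from every
  per-sensor coefficient — changes no prediction, so the gauge choice is
  irrelevant; tests assert this invariance, the stationarity of the
  normal-equation gradient, and prediction agreement with an independent
  pseudoinverse oracle to 1e-8 mm.
- `normalized` (evaluation default): predictors are the force fractions
  F_i / F_tot (12 columns). Predictions are invariant to rescaling all
  forces, which is also an exact property of the true COP (a ratio of
  first moments to total load).

**Why `normalized` is the evaluation default.** The true COP is a
degree-0-homogeneous function of the pressure field: doubling all forces
moves it nowhere. The `linear` form is degree-1 homogeneous, so whenever
total load varies materially within a recording — as it does by design in
the sit-to-stand and stand-to-sit tasks, where foot load ramps between
roughly a third of body weight and full body weight — no coefficient
vector can track the COP exactly, and the residual error scales with the
absolute coordinate values. On the simulator this is not a small effect:
for an ideal noise-free subject the `linear` variant's cross-validated AP
RMSE is tens of millimetres while the `normalized` variant's is at
floating-point level (the test suite computes both). Real recordings give
the linear form more to work with (each sensor is a genuinely independent
channel, while the simulator's forces live on a low-dimensional manifold),
but the scale-invariance argument holds regardless, so the package
evaluates and compares estimators with the ratio form by default. The
13-column linear system remains fully implemented and tested, including
its rank-deficiency structure; `fit_cop_model` uses it as its default
because it is the canonical normal-equations formulation.

Coordinate-seeded initial coefficients (sensor x- or y-positions, 0 for
the total-force entry) are recorded in the fitted model as provenance.
They do not affect the closed-form solution; they exist because the
natural starting point of any iterative scheme for this problem is the
weighted-mean geometry, and keeping them makes fitted models
self-describing.

## Calibration

FSR channels map acquisition-chain voltage to force through a per-sensor
fourth-order polynomial, evaluated by Horner's scheme and floored at 0 N.
`fit_calibration` fits such polynomials from bench (voltage, force) pairs
by least squares, requires at least degree+1 distinct voltages, reports
the residual RMS, and sets the valid range to the span of the calibration
voltages. Out-of-range voltages at apply time are clamped with a logged
warning rather than raised, because transient spikes are routine in
practice. The shipped default polynomial is synthetic and intended for
simulation and demos only; real deployments must supply their own
per-sensor calibration JSON. Creep and hysteresis conditioning of FSRs is
out of scope.

## Evaluation protocol

Each subject-foot contributes 6 tasks x 3 trials. Fold k contains trial k
of every task, so every fold is task-complete; a seeded random assignment
mode exists for robustness checks. For each of the three rotations the
model is fitted on the two training folds concatenated and evaluated on
the test fold; the weighted mean needs no fitting. Metrics per fold and
axis, computed on the concatenated test trajectory:

- RMSE (mm);
- Pearson correlation with its two-sided p-value (t-distribution, n-2
  degrees of freedom, via `scipy.stats.pearsonr`);
- MaxE / MinE: the maximum and minimum per-sample absolute error (mm).
  These are whole-evaluation-set extremes per axis, which is why MaxE is
  typically an order of magnitude above RMSE — it is dominated by the
  worst transient of the hardest task.

Aggregates are mean +/- SD across the three folds; cohort-level summaries
average the per-fold means per subject-foot. Estimate and reference are
assumed time-aligned; hardware synchronisation is not modelled.

## Synthetic data

**Pressure model.** The plantar load is a mixture of K = 9 blobs pinned to
anatomical loci (heel, midfoot, five metatarsal heads, great toe, lesser
toes). Per frame the blob amplitudes are non-negative, sum to the
prescribed total load, and define the ground-truth COP in closed form as
the amplitude-weighted centroid of the loci. Given a target COP path and
load profile, amplitudes are recovered by exponential tilting of a
baseline load-share vector (softmax over the loci), with the 2-vector tilt
solved per frame by damped Newton iteration on the centroid-matching
condition (Levenberg-damped 2x2 solve, step-norm cap 0.5, tolerance
1e-9 mm, max 300 iterations). Tilting keeps amplitudes strictly positive
and is exact for any target strictly inside the convex hull of the loci;
target paths are first clamped onto a 5 mm-inset hull (convex-hull
polygon, shapely projection). The forefoot loci span ML 25-82 mm so the
inset hull admits the full ML mean +/- SD band the task targets prescribe.

**Sensor model.** Each blob's load is apportioned across the twelve
(placement-perturbed) sensor positions by Gaussian proximity weights
(default kernel width 25 mm) normalised to sum to one per blob — i.e. the
array registers the full regional load, divided by proximity. This choice
makes the total measured force of an ideal subject equal the true total
load exactly, and makes the ground-truth COP an exactly linear function of
the normalised predictors, which is what gives the noise-free recovery
tests a sharp (1e-6 mm) target. It deliberately omits the partial-
registration error of real sparse arrays (load landing between sensors and
vanishing), which is one mechanism behind weighted-mean error in practice;
in the simulator, weighted-mean error comes instead from gain spread,
placement offsets, the geometric mismatch between blob loci and sensor
positions, noise and quantisation. A subject profile applies per-sensor
log-normal gains (median 1, sigma 0.2 by default), Gaussian placement
offsets (sd 3 mm), optional compressive response exponent (default 1 =
linear), additive Gaussian noise (sd 0.3 N), a non-negativity floor, and
10-bit quantisation over a 100 N full scale.

**Tasks.** Quiet standing (10 s): COP sway is white noise filtered by a
second-order 1 Hz low-pass (the dominant band of quiet-stance
stabilograms; the cutoff is a modelling choice, not a measured value),
then rescaled so the realized per-axis range and mean equal the per-trial
targets — targets are inputs, not predictions. Transitions (5 s): a
deterministic anterior-excursion shape and a load-fraction profile
(PCHIP through knots; sitting plateau 0.35 of per-foot weight, seat-off
peak 1.10 without armrests vs 0.60 with, standing 1.0; sit-downs are the
time reverse) plus filtered-noise wobble, rescaled the same way. Per-trial
range and mean targets are drawn from the task defaults' mean +/- SD,
truncated at +/-30 % of the mean so that hull clamping stays mild. Task
default ranges: quiet standing ML 2.5 / 8.7 mm and AP 6.9 / 16.4 mm (eyes
open / closed); transitions ML 12.8-16.3 mm, AP 67.0-73.2 mm; mean COP
near (42-48, 187-209) mm. Body weight is drawn per subject
(N(650, 60) N, clipped to [400, 1000]); one insole carries half of it.

**Seeding.** All randomness descends from a master seed through a
splittable seed tree (cohort -> subject -> profile/trials -> trial ->
path/sensor), so any single trial is bit-reproducible in isolation and the
same master seed yields an identical cohort.

**What passing tests do and do not show.** The simulator's forces live on
a low-dimensional manifold (2 COP coordinates + load), its blobs never
truncate at the insole boundary, its noise is white and Gaussian, and its
sensors have no creep, hysteresis or saturation. Results on it demonstrate
the correctness of the estimators, the evaluation harness and the claimed
invariances — not field accuracy on real feet. In particular the fitted
model's sub-millimetre cohort RMSEs are a property of the simulator's
idealised forward model; on real recordings, published errors for this
class of system are millimetres ML and around a centimetre AP.

## Problem sizes

Default test and acceptance runs use cohorts of up to 50 subjects x 18
recordings (500 frames per quiet trial, 250 per transition), 200 random
instances for the solver-oracle check (m up to 1000), and 10 trials per
task for the range-calibration check. A full acceptance run completes in a
few seconds on one CPU.

## Known limitations

- No gait or stair tasks; the battery is static stance and chair
  transfers only.
- No time-lag/dynamics modelling, no regularised fitting, no
  cross-subject transfer.
- Calibration polynomials are per-sensor configuration inputs; the
  package does not model the FSR's voltage-divider electronics.
- The evaluation assumes pre-aligned estimate/reference series.
- MaxE/MinE definitions (per-sample absolute error extremes per axis over
  the evaluation set) are one reasonable reading of common practice;
  other aggregations exist.
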