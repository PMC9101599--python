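# Methods

## The assessment pipeline

`wristkin` models a robot-assisted wrist assessment: a subject holds the
end-effector of a planar haptic device and traces a displayed closed curve
clockwise, under a resistive force of 0, 1.5 or 5 N, while the device
samples the handle position in the X-Y plane. Each subject performs the
task for three shapes × three force modes. Kinematic features extracted
from each trial are regressed onto a clinician's wrist motor-function
score (14 items × 0–2 points, range 0–28; higher = less impaired).

## Reference curves

Curves are closed polylines centered on the workspace origin, clockwise
(negative shoelace area), resampled to arc-length-uniform vertices so that
nearest-point queries are well conditioned. The square is axis-aligned and
the triangle equilateral with one vertex up — arbitrary but fixed choices
kept for reproducibility. `size` (default 8 cm: side length, or circle
diameter) must fit the 10 × 10 cm workspace; the triangle is the binding
case (circumradius `size/√3` ≤ 5 ⇒ size ≤ 8.66 cm). When the vertex count
does not divide evenly among a polygon's sides, resampling can shift the
area centroid by ~10⁻⁵ cm; vertices are re-centered after resampling so
the centroid sits on the origin to machine precision. The polygonal
circle's perimeter is `n·d·sin(π/n)`, within 0.1 % of πd for n ≥ 64.

## Synthetic cohorts

Clinical recordings of this kind are not publicly distributable, so the
package generates surrogate cohorts. The generator is first-class, tested
code, and its defaults define the study conditions:

* **Cohort structure** — 25 patients (one tested hand, 9 trials) and 10
  controls (both hands, 18 trials): 405 trials. Patient scores are drawn
  from the empirical pool of the recruited patient cohort (range 5–24);
  control scores from {26, 27, 28} (control scores are not reported
  clinically; the ceiling pool is an assumption and is configurable). A
  `"uniform"` sampler (scores 0–28) is available for experiments that need
  the full scale covered.
* **Impairment mapping** — severity `s = (28 − score)/28` maps to: tremor
  amplitude `0.5·j·s^1.1` cm, drift amplitude `0.8·j·s` cm, speed scale
  `1/(1 + 2j·s)`, pause probability `0.08·s`, with `j ~ U(0.85, 1.15)` a
  per-subject jitter drawn from the seed only. Because the jitter does not
  depend on the score, the mapping is exactly monotone at fixed seed, and
  score 28 yields literally zero distortion (the healthy path lies on the
  curve to machine precision).
* **Trial synthesis** — the curve is traversed once, clockwise, with a
  monotone time-warp: a smooth pace modulation (±5 % when healthy,
  deepening to ±30 % at maximum severity), occasional pauses, and an
  overall slowing of `1/speed_scale`; a resistive-force term mildly
  prolongs impaired trials. On top of the warped path: a signed radial
  drift (≤ drift amplitude), two tremor sinusoids in the 4–8 Hz band, and
  white position noise at 4 % of the tremor amplitude. The healthy pace
  modulation exists because real unimpaired movement is not
  constant-speed; without it the speed profile is numerically flat and the
  peak-velocity count degenerates into counting float ripple.
* **Determinism** — all fixed-shape random draws are consumed before any
  draw whose size depends on severity, so two profiles differing only in
  score share the same noise waveforms, scaled. This makes "strictly more
  impaired ⇒ strictly larger deviation" a well-posed, testable statement
  rather than a statistical tendency.
* **Sampling** — default 200 Hz rather than the device's 1 kHz; the
  features are rate-invariant after smoothing, and 200 Hz keeps a full
  cohort cheap (~0.6 s to simulate, ~1 min to featurize). Device-rate data
  are available via `sample_rate=1000`.

What the simulator does **not** emulate: realistic haptic/limb dynamics,
shoulder-elbow compensation, inter-trial learning, asymmetric hand
performance, or heteroscedastic clinician scoring noise. Passing tests
therefore demonstrate that the pipeline recovers scores when the
score→kinematics mapping is monotone and low-noise — an upper bound on, not
a prediction of, clinical performance.

## Features

For one trial with N samples:

* **Velocity profile** — positions are smoothed by a centered moving
  average (default 50 ms; configurable, 0 disables) and differentiated by
  central differences (one-sided at the ends). `Vᵢ` is the speed; `Aᵢ` is
  the magnitude of the acceleration *vector* — a signed scalar dV/dt would
  average to ≈0 over a closed loop and carry no information.
* **NPV** — "points on the velocity curve above the mean speed" is
  ambiguous: counting *samples* makes the feature proportional to the
  sampling rate. Default mode counts strict local maxima of the speed
  curve exceeding the mean (the sub-movement reading of the motor-control
  literature); `npv_mode="literal"` retains the per-sample count.
* **D** — mean Euclidean distance from each sample to the curve, using
  exact segment projection (shapely), not vertex-only distance.
* **C** — a path segment is coincident when both endpoints lie within ε of
  the curve; C = 100·L꜀/Lᵣ. ε is a free parameter of the metric (no
  physical tolerance is prescribed); default 0.25 cm, reported in all
  outputs. Note the ceiling: when the whole path stays inside the ε-band
  (scores ≳ 22 under the default simulator), C = 100 regardless of score,
  so C only discriminates beyond mild impairment.
* **S** — the traced path is closed (last→first sample), cleaned of
  self-intersections (`shapely.make_valid`, even-odd style), and S is the
  area of the symmetric difference between the enclosed region and the
  curve's region — the sum of all pocket areas between the two closed
  paths. A path enclosing no area (degenerate trace) counts as a full
  miss: S falls back to the curve's own area, with a warning.
* **T** — last minus first timestamp.

All seven features are invariant under rigid motions applied jointly to
recording and curve (tested to 1e-9).

## Normalization, split, models

Features are z-scored with the *population* standard deviation. Statistics
are fitted on the training split and applied to both splits (no leakage);
fitting on the whole dataset first is available as a compatibility option.
The default split is per-trial (70/30: 283/122 of 405) — with per-trial
splitting, trials of one subject can appear on both sides, which inflates
apparent accuracy; a subject-level split is provided as the conservative
alternative.

Model defaults (tunable; the method itself prescribes only the BPNN
architecture, SGD and ReLU):

| model | defaults |
|-------|----------|
| rf    | 200 trees, unlimited depth |
| svr   | RBF kernel, C = 10, ε-tube 0.1 |
| knn   | K = 5, uniform weights, Euclidean distance over all 7 features |
| bpnn  | layers 7-56-28-7-1, ReLU, SGD, lr 0.01, 500 epochs, batch 16 |

Numerical choices worth knowing:

* The BPNN is trained on standardized targets (`TransformedTargetRegressor`
  + `StandardScaler`) and predictions are mapped back to the score scale.
  With raw 0–28 targets, constant-rate SGD through ReLU units is unstable
  at these learning rates (loss plateaus or units die); standardizing the
  target makes the stated defaults converge reliably.
* KNN distance ties are broken by training-set order after a seeded
  shuffle, making predictions reproducible and invariant to the caller's
  row order. A `feature_subset` option restricts the distance to a subset
  of the seven features.
* Predictions are clipped to [0, 28]; the scale has no meaning outside it.
* RF feature importances are mean impurity-decrease values normalized to
  sum to 1.

## Evaluation

Accuracy counts |y − ŷ| ≤ tol as correct (tol = 3 scale points by default;
the boundary is inclusive, matching the clinical "within 3 points"
convention). MAE, MSE and R² = 1 − SS_res/SS_tot are computed directly;
Pearson/Spearman correlations (average ranks for ties — integer labels
guarantee ties) come from scipy with two-sided t-approximation p-values.
R² may be negative; it is undefined (error) for constant truth.

## Verification strategy and problem sizes

Geometric operations are tested against independent oracles: nearest
distances against a brute-force 10⁵-point densification of the curve
(KDTree), areas against seeded 10⁶-point Monte-Carlo rasterization using
matplotlib's point-in-polygon test (independent of the shapely
implementation path), metrics against direct summation, and derivatives
against analytic kinematics (uniform and circular motion). The end-to-end
check trains all four models on a 405-trial cohort with uniformly drawn
scores and requires ≥ 85 % tolerance-3 accuracy from each, plus |r| > 0.5
feature-score correlations with coincidence positively signed. Cohort
sizes, sampling rates and Monte-Carlo budgets in the test suite are chosen
so the whole suite completes in a few minutes on one CPU.

## Known limitations

* Synthetic accuracies (~95–100 %) exceed clinically reported values for
  this protocol family (~88–94 %): the simulator's score→distortion map is
  deterministic and monotone, and per-trial splitting shares subjects
  across splits.
* C saturates at 100 % for mild impairment (see above); ε trades
  sensitivity at the healthy end against noise rejection at the impaired
  end.
* The intersection-area cleaning resolves self-crossing paths even-odd;
  paths that loop over the same pocket twice are counted once.
* Force mode affects the simulator only as a mild slowing of impaired
  subjects; no haptic dynamics are modeled, and force is not a model
  feature.
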