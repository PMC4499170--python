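# Methods

`pulsefactor` re-implements, as a reusable and fully testable pipeline, a
wrist-pulse-wave analysis of hypertension: tonometric pressure-sweep
recordings at the Gwan position of both wrists are reduced to ten
"physical factors" per wrist, which are then related to hypertension
status by standardized-odds-ratio logistic regression and evaluated as
predictors with cross-validated naive-Bayes and logistic classifiers,
including wrapper and LASSO feature selection.  Because the original
cohort (393 Korean women, 341 normotensive / 52 hypertensive) is not
public, every stage runs against synthetic data whose generators are
first-class, tested components of the package.

## The waveform simulator

A beat is modelled as three positive Gaussian lobes on a zero baseline —
percussion, tidal and dicrotic waves — parameterised by fractions of the
beat duration (`BeatModelParams`).  Two constructions make the template
exactly analysable:

* the **dicrotic lobe height is solved analytically** from the condition
  that the waveform be stationary at `notch_position`, so the dicrotic
  notch (the systole/diastole boundary) is planted to sub-sample
  accuracy rather than emerging approximately from lobe overlap; the
  `lobe_heights[2]` entry is only a fallback when that linear solve has
  no positive solution;
* the small percussion-tail offset at the beat start is removed with a
  fast-decaying Gaussian correction, so every beat leaves 0 V exactly
  with a smooth takeoff and never dips below its foot.  Without this the
  baseline between beats is ill-defined and foot detection becomes
  ambiguous.

Defaults: lobes at (0.15, 0.30, 0.55) of the beat with widths
(0.075, 0.110, 0.070) and heights (1, 0.55, ·), notch at 0.44, amplitude
3.1 V (the normotensive left-wrist pulse amplitude), 75 bpm.  The tidal
lobe is deliberately broad so it forms a physiological shoulder rather
than a separate peak; the template has exactly one interior local
minimum (the notch) before 60% of the beat.

A pressure-sweep recording (`SweepParams`) stacks one multi-beat channel
per hold-down step.  Pulse amplitude is unimodal in hold-down depth; we
use a Gaussian profile over step index peaking at `optimal_step` (width
1.8 steps), so the planted sensor displacement at maximal pulse pressure
is `optimal_step × step_displacement` mm.  Respiratory baseline wander
is a 0.25 Hz, 0.15 V sinusoid and sensor noise is white (0.02 V).  The
source device's step size and step count are not published, so the
defaults (7 steps of 1 mm at 200 Hz, 30 s per step) are declared
choices, mirrored by the reference displacement statistics (~6 mm mean
at maximal pulse pressure).  Every recording carries a truth-manifest
entry (planted pulse amplitude, displacement, systolic area, heart
rate, class).

## The cohort simulator

`CohortSpec` holds per-class Gaussian marginals for the 20 factors and
the demographics; its defaults equal the published per-class means/SDs
of the reference cohort exactly, with class sizes 341/52.  Factors are
drawn independently per class — the source publishes no covariance, and
single-factor targets need only the marginals — with an optional
Gaussian copula (scalar exchangeable or full matrix) for
feature-selection experiments.  Blood pressures are drawn from the
class-conditional Gaussians and rejection-sampled onto the correct side
of the diagnostic rule (SBP ≥ 140 mmHg or DBP ≥ 90 mmHg), so labels and
pressures are consistent by construction.  What this simulator does
*not* emulate: inter-factor correlation (by default), non-Gaussian
tails, and measurement artifacts; passing tests therefore demonstrate
the statistical machinery and the marginal structure, not the joint
distribution of real cohorts.

## Preprocessing

Cleaning chain per hold-down step: zero-phase Butterworth band-pass
(order 4, forward-backward), beat-foot onset detection, cubic-spline
baseline removal anchored at the feet, beat segmentation into half-open
`[onset, next onset)` spans.  Design notes:

* **Band corners default to [0.3, 35] Hz.**  The low corner must sit
  well below the slowest plausible pulse fundamental (0.67 Hz at
  40 bpm): a 0.5 Hz corner already attenuates sub-1-Hz fundamentals by
  ~2% after forward-backward filtering.  The high corner must sit well
  above the beat's harmonic content (≤ ~15 Hz): a 20 Hz corner leaves
  visible ringing at the sharp beat foot that biases area factors by
  ~1%.  Both corners are arguments on every function.
* **Onsets**: prominent peaks of the first derivative (minimum spacing =
  one beat at 180 bpm) mark the upstrokes; the foot is found by a
  threshold crossing (4% of the local pulse height above the local
  minimum) followed by a walk-back to the nearest local minimum.  A pure
  windowed argmin is ill-posed here because the inter-beat baseline is
  nearly flat, and ripple minima up to tens of milliseconds early would
  be selected.
* **Baseline**: a cubic spline through the foot values, subtracted over
  the whole record, re-anchors every onset to ~0 V; anchoring at beat
  feet (rather than fixed-interval knots) ties the baseline estimate to
  the breathing-coupled wander it removes.  The operation is idempotent
  and exact on drift-free input.
* **Step selection**: the step with maximal median per-beat peak-to-foot
  amplitude wins; ties go to the smaller displacement; a maximum at the
  deepest step triggers a "sweep did not bracket maximum" warning.

## The ten factors

With PPI the median per-beat peak-to-foot amplitude (V) and PDI the
winning displacement (mm):

* Area sums use exact piecewise-linear threshold geometry: over the
  region where the signal exceeds a threshold θ, `S_full = ∫ signal dt`,
  `S_above = ∫ (signal − θ) dt` and the time above `T` satisfy
  `S_full − S_above = θ·T` to machine precision (the identity is used as
  the definition of `S_full`).  Thresholds: 0.3·PPI (relative) and the
  1.12 V absolute detection voltage; sums are totals over all beats of
  the analysed window (the published magnitudes, ~80–100 V·s, imply
  multi-beat summation), so they scale with window length (default
  30 s per step).
* The systolic area integrates onset → dicrotic notch and is normalised
  to 75 bpm by a linear time rescale (× HR/75).  The notch is the first
  local minimum after the systolic peak within 60% of the beat, with a
  documented fallback at 40% of the beat (warned).  The per-recording
  value is the **median** over beats — a robust average chosen because
  occasional split/merged beats at segmentation would corrupt a plain
  mean — after dropping the first and last beats, which sit in the
  zero-phase filter's edge transients.
* Spectral factors come from a Welch density (Hann window, 50% overlap,
  ≤ 0.25 Hz resolution, one-sided, Vrms²/Hz): the density maxima within
  ±0.3 Hz of the heart-rate fundamental and its double, and the
  trapezoidal 0–13 Hz band power.  The density-at-peak-bin convention
  (vs integrated peak power) is a declared choice; absolute magnitudes
  of the spectral factors are device-dependent and are not calibrated
  to the published units.

## Association analysis

Hypertension is SBP ≥ 140 mmHg or DBP ≥ 90 mmHg; normotension is the
complement (the two classes partition the sample).  Each factor is
z-scored over the full sample (n−1 SD), so odds ratios are per SD and
invariant to affine rescaling of the raw factor.  Crude model:
logit(hypertension) ~ z(factor); adjusted adds z(age) + z(BMI).  Fits
are maximum likelihood (Newton/IRLS, tolerance 1e-8, ≤100 iterations;
statsmodels backend); perfect separation raises an explicit error.
Confidence intervals and p-values are Wald with the 1.96 multiplier,
matching the `OR (CI)` reporting format; whether the original analysis
used Wald or likelihood-ratio tests is unstated, Wald is assumed.  Rows
with missing analysis columns are dropped and counted in the log.

## Prediction and selection

Classifiers: Gaussian naive Bayes (class priors = training frequencies,
variances floored at 1e-9 of the dominant feature variance) and
unpenalized logistic regression.  Evaluation: stratified 5-fold CV with
a fixed, logged seed; the out-of-fold posterior probabilities are pooled
into a single ROC — with only 52 positives, per-fold AUCs are too noisy
to average — and the AUC equals Mann-Whitney U/(n₀n₁), ties counting
half.  Per-class sensitivity, false-positive rate, precision and
F-measure are computed one-vs-rest at a 0.5 posterior threshold (the
usual default; the source does not state one), with undefined precision
reported as 0 and flagged.  No class rebalancing is applied, matching
the stated class-imbalance handling of the original analysis.

Wrapper selection enumerates all non-empty subsets (1,023 for ten
factors) with the *same* fold assignment, maximising pooled CV-AUC; ties
break to the smaller subset and then lexicographic factor order.  LASSO
selection minimises stratified 5-fold CV deviance over a 50-point
log-spaced penalty grid spanning four decades below the data-derived
λ_max, takes the nonzero support of the full-data fit at the chosen
penalty (L1 logistic via the saga solver, unpenalized intercept), and
refits unpenalized logistic regression on the support; if the chosen
penalty selects nothing, the largest penalty retaining at least one
factor is used (logged).  Selection is not nested inside the evaluation
folds, matching the apparent original workflow; both the fold seed and
the nesting choice are configurable.

Known behaviour worth stating plainly: on toy problems with one
informative and several noise features, the wrapper always keeps the
informative feature but picks up a chance noise feature in a sizeable
minority of runs (pooled-OOF-AUC ties are broken by luck), and the
minimum-CV-deviance LASSO rule is liberal — it retains several noise
features while always keeping at least one of a correlated informative
pair.  The tests assert these true properties rather than idealised
selection rates.

## Reproducing the published single-factor AUCs

The published per-subject data are unavailable, so Tables of per-factor
AUCs are reproduced *distributionally*: cohorts are drawn from the
published per-class Gaussians and pushed through the actual CV
machinery.  For a single Gaussian factor the closed-form binormal AUC
Φ((μ₁−μ₀)/√(σ₀²+σ₁²)) is the oracle — e.g. 0.698 for the left-wrist and
0.755 for the right-wrist pulse amplitude — and the simulated mean
pooled CV-AUC over 200 seeded replicates of the 341/52 cohort is
compared against the published values (0.700/0.763/0.759/0.648/0.671)
at ±0.03.  Pooling the out-of-fold scores costs ~0.005 AUC relative to
the raw-feature AUC; both effects are visible in the acceptance output.
The published combined-model tables and odds-ratio point values depend
on the real cohort's joint covariance and are **not** desk-reproducible;
their builders are validated by shape and invariants instead.

## Problem sizes and budgets

Simulation sizes are chosen so the full test suite runs in about a
minute: 200 cohort replicates for the AUC reproduction, 1,000 replicates
at n = 400 for Wald coverage, 1,000 random tied inputs for the
AUC/Mann-Whitney identity, 50 randomized noiseless recordings (heart
rates 55–95 bpm, amplitudes 2–4.5 V, 20 s per step) for planted-truth
recovery, and 15–20 Monte-Carlo replicates for the selection
properties.  `scripts/acceptance.py` recomputes the headline quantities
from scratch with seeds derived from `--seed`.

## Limitations

The waveform model is a descriptive three-lobe shape, not a
hemodynamic model (no Windkessel or arterial-tree physics, no ECG
reference); the cohort simulator reproduces marginals only; spectral
factor magnitudes are not calibrated to the source device; and the
synthetic link between class and waveform (a single amplitude
multiplier) is far simpler than real hypertensive hemodynamics.
Conclusions about real cohorts require real recordings in the
documented HDF5 layout or factor tables in the documented CSV schema.
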