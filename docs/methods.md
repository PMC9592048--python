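# Methods

## Problem and model

`gaitprognosis` implements a prognostic-classification pipeline for inpatient
stroke rehabilitation: predict, from data available in the first week after
admission, whether a patient will be a **household** (10 m walk speed
< 0.4 m/s) or **community** (≥ 0.4 m/s) ambulator at discharge.  Three input
families are used: patient information (PI: demographics and stroke
characteristics), admission functional-assessment scores (FA: 10MWT, 6MWT,
BBS, TUG, FIM motor), and features computed from three body-worn IMUs
(pelvis and bilateral ankles, ±4 g accelerometer and ±2000 °/s gyroscope at
31.25 Hz) recorded during a short walking bout.  Model variants are named by
the feature families they use: PI+FA (the clinical benchmark), PI+IMU,
PI+FA+IMU, and PI (near-chance by construction, kept behind a flag).

The clinically decisive sub-population is the small group of patients who
*recover* community ambulation during the stay (household at admission,
community at discharge).  An admission-speed benchmark necessarily labels
them household; the working hypothesis of the pipeline is that movement
quality measured at admission — motion amplitude and cycle complexity —
carries the extra prognostic signal.

## Signal features

All inertial features are computed on the Euclidean magnitude of the
tri-axial signal, which makes them invariant to sensor orientation.  Per
sensor and per signal (accelerometer, gyroscope) the statistics are: mean,
SD (n−1), skewness, excess kurtosis, RMS, range, IQR, median, and sample
entropy; the gyroscope additionally yields the amount of motion
(AoM = Σ‖ω_t‖/f_s, the rectangular-rule time integral of angular speed, in
degrees).  The default catalog is 9 PI + 5 FA + 57 IMU = 71 features
(3 sensors × 2 signals × 9 statistics + 3 AoM), namespaced `PI.*`, `FA.*`,
`IMU.<placement>.<signal>.<statistic>` and overridable in configuration.

Sample entropy uses the physiological-signal conventions m = 2 and
r = 0.2·SD (population SD), with Chebyshev template distance, self-matches
excluded, SampEn = −ln(A/B).  A zero-variance series returns 0; a series
with no (m+1)-template matches returns +inf.  The implementation is a
block-vectorised exact pair count (no approximation); tests verify it
against an exhaustive O(n²) enumeration to 1e-12.

Two bout paradigms are supported: *fixed distance* (the 10 m walk; for
synthetic data the first ⌊(10/v)·f_s⌋ samples of a constant-speed bout, for
real annotated trials the whole recording) and *fixed duration* (the first
10–360 s of a six-minute walk, durations restricted to the set
{10, 20, 30, 60, 90, 120, 180, 240, 300, 360} s).  No filtering or
detrending is applied before feature computation.  Categorical PI fields use
fixed integer codes (documented in `features.CATEGORY_CODES`); tree
ensembles are invariant to the coding.  Missing assessment scores are
imputed as 0, the convention for patients unable to complete a test.

## Classifier

The cohorts are small (tens of patients) and imbalanced (roughly 27
community / 6 household), so the workhorse is a **balanced random forest**:
each tree is grown on a bootstrap (with replacement) of the minority class
plus an equal-sized undersample (without replacement) of the majority class,
making every per-tree training multiset exactly class-balanced.  Aggregate
probability is the mean of per-tree probabilities; an exact 0.5 tie predicts
the minority (household) class — the clinically conservative call, since a
household prediction triggers discharge support planning.

Internally each tree is a CART *regression* tree on the 0/1 class
indicator: for a binary target, variance-reduction splits coincide with
Gini splits, leaf means are class probabilities, and impurity importances
are identical, while per-tree fitting avoids repeated label-validation
overhead — relevant because the seed-averaging protocol fits hundreds of
thousands of trees.  The estimator follows the scikit-learn contract
(`fit`/`predict`/`predict_proba`, `get_params`, `feature_importances_`) and
composes with `RFECV` and `RandomizedSearchCV`.  `max_features` accepts
"sqrt", "log2" and "auto" (alias of "sqrt", the historical classification
default).  Alternative imbalance-aware estimators can be supplied anywhere
an estimator is accepted, for algorithm-comparison studies.

## Optimization protocol

Per variant and paradigm, in order:

1. **Correlation filter** — zero-variance columns are dropped, then feature
   pairs are scanned in catalog order and the later feature of any pair with
   |Pearson r| > 0.9 is dropped (the tie rule is catalog-order based; an
   audit log of (kept, dropped, r) triples is retained).
2. **Importance aggregation** — RFECV (elimination step 1, stratified
   5-fold internal CV, weighted-F1 scoring) is repeated over incremented
   seeds; each run's impurity importances (0 for unselected features) are
   summed across runs and normalized to 1.
3. **Backward elimination** — for k from the surviving feature count down
   to 1, the top-k features by aggregated importance are scored by
   seed-averaged LOSO weighted F1 with default hyperparameters; the argmax
   subset is kept, ties resolving to fewer features.
4. **Hyperparameter tuning** — repeated `RandomizedSearchCV` (stratified
   5-fold, weighted F1) over n_estimators, max_depth, min_samples_split,
   min_samples_leaf and the max_features mode; the configuration winning the
   most repetitions is chosen (ties to the earliest seed).
5. **Evaluation** — leave-one-subject-out CV repeated over incremented
   seeds; mean ± SD of weighted F1, accuracy, and AUROC (community-class
   probability, one LOSO score per patient per seed, AUROC computed per seed
   then averaged); the modal confusion matrix across seeds; a flag for
   whether any per-patient label fluctuated across seeds; and the
   per-transition-group recall of the modal predictions.

Selection and tuning deliberately use the full cohort before the LOSO
evaluation — a single aggregate model is easier to interpret, at the cost of
optimistic bias from train/test leakage.  The package reproduces this
protocol as specified; a nested leak-free variant is out of scope.

Seed schedules are `base, base+1, …` with the base taken from the experiment
master seed, so every stage is independently reproducible and the whole run
is determined by the configuration hash plus the master seed.

## Synthetic cohort generator

No patient data ship with the package; a generator produces cohorts with the
statistical structure the analysis assumes.  Composition is configured as
three transition groups; the default is 6 household→household,
23 community→community and 4 household→community patients — 33 patients,
27 community / 6 household at discharge, matching the reference cohort's
discharge split with a recovering subgroup of four.

Admission and discharge 10 m speeds are truncated normals per group
(household-stable: 0.22±0.08 → 0.27±0.07 m/s capped below 0.4; stable
community: 0.85±0.25 → 1.00±0.25 m/s floored at 0.4; recovering: 0.24±0.07
→ 0.82±0.30 m/s), chosen to bracket the individual admission/discharge
speeds reported for such patients (0.17–0.33 m/s admission, 0.54–1.27 m/s
discharge).  Gait-quality parameters are drawn conditional on the
*discharge* class — community-bound patients have larger ankle swing
amplitude (170±25 vs 95±20 °/s), larger pelvis acceleration amplitude
(0.25±0.05 vs 0.12±0.03 g), higher cycle irregularity (0.35±0.08 vs
0.12±0.04; higher movement complexity with functional recovery), and less
asymmetry (0.20 vs 0.40) — encoding the premise that admission movement
quality is prognostic.  Cadence is tied to admission speed
(0.9 + 0.9·v ± 0.08 steps/s).  PI covariates are drawn independently of
class by default so PI-only models sit near chance; a config flag makes age
class-informative for ablations.  FA scores are monotone functions of
admission speed plus noise, clipped to their clinical ranges — informative
about the *admission* class, hence systematically misleading for the
recovering group.

Signals are jittered sums of two harmonics, not a biomechanical model: the
features in scope depend only on amplitude, periodicity and irregularity
structure.  Ankle gyroscopes oscillate at stride frequency (cadence/2) with
peak ≈ swing amplitude (scaled by 1−asymmetry on the affected side); the
pelvis accelerometer oscillates at step frequency around a constant 1 g
gravity offset on its vertical axis (ankle sensors carry the offset on x,
matching the rotated mounting).  Cycle periods and amplitudes are jittered
per cycle in proportion to `irregularity`; Gaussian sensor noise (0.02 g,
2 °/s) is added; outputs are clipped to the device ranges.  The six-minute
bout applies a fatigue drift: amplitude decays and irregularity grows by
`fatigue_drift` per minute (amplitude floored at 30 %).  Everything is
deterministic given the cohort seed (per-patient seed streams are spawned
from a `SeedSequence`).

What the generator does **not** emulate: gait initiation/termination
transients, turning, rest breaks in the six-minute walk, axis-resolved
biomechanics, assistive-device signatures, non-ambulatory activity, and any
within-class correlation between PI and outcome.  Passing tests therefore
demonstrate that the pipeline recovers class structure of the kind assumed,
not that it would perform identically on real recordings.

## Study sizes and numerical choices

The package's standard desk-scale study (`pipeline.default_study_config`)
uses 20 RFECV repetitions, 5 seeds per backward-elimination point, a 5×10
randomized hyperparameter search, and 20 evaluation seeds on the 33-patient
default cohort; all counts are configurable upward (the original protocol
used 100 everywhere).  SD over seeds uses the population convention (so a
single-seed run reports SD 0).  Recording CSVs are written with `%.17g` and
read with round-trip float parsing, making file-mode ingestion of
synthetic-mode output bit-identical.  Metric edge cases: per-class F1 is 0
when precision+recall is 0; all-zero confusion matrices are rejected;
AUROC requires both classes.

## Known limitations

- The leaky optimize-then-evaluate protocol (see above) overstates absolute
  performance; only model *comparisons* under the same protocol are
  meaningful.
- With few minority patients, stratified 5-fold internals are near their
  validity limit (≥ 5 minority members required).
- The backward-elimination curve uses default hyperparameters; tuning
  happens after subset selection, so the curve and the tuned model are not
  jointly optimal.
- Real IMU walking data contain structure (turns, pauses, drift) the
  generator does not produce; feature distributions will differ in scale.
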