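# Methods

## The task and its observables

One "movement" is a cycle of placing the preferred foot on a stepper and
returning it to the ground. The foot-height trace of a cycle shows two
peaks — a larger one stepping up and a smaller one lifting off to return —
separated by an interval with the foot on the stepper. Hip and knee flexion
co-vary roughly proportionally along a single coordination path. Practice
is organised in blocks of 10 movements, five blocks per step-height
condition, two conditions whose heights are titrated by perceived
challenge. The raw observables per recording (one block) are 7 joint-angle
channels in degrees relative to the static anatomical position, vertical
foot position and vertical hip position in metres, at 120 Hz.

## Preprocessing and segmentation

Signals are low-pass filtered with a 4th-order Butterworth applied forward
and backward (zero phase; effective 8th-order magnitude response) at 6 Hz.
"Fourth-order, zero-lag" is read as 4th-order coefficients run twice, the
standard biomechanics convention.

Movement onset is the first frame whose **raw** foot height exceeds the
mean of the first ten frames plus ten times their SD (strict inequality;
with a constant baseline the SD is 0 and the threshold degenerates to the
baseline itself). The onset is taken from the raw trace because zero-phase
filtering both shrinks the baseline SD and spreads movement energy
backwards in time, which makes the filtered-trace threshold fire during
rest.

Between-movement boundaries are peaks of the inverted filtered foot trace
with a minimum separation of 200 frames and height strictly above the
trace mean; peak foot height per movement uses the mirrored rule. The
200-frame window is interpreted as a minimum peak separation (the
alternative fixed-search-window reading is noted in the configuration).
Candidate segments that contain no detected foot-height peak are discarded
— they are rest periods, not movements. A block whose final cycle count
differs from the expected count is flagged in a QC table; nothing is
corrected by hand (the original procedure's visual inspection is replaced
by this flag plus an optional per-movement frame-override file).

Cycles are time-normalised to 100 samples by linear interpolation. Per
movement we record the (hip, knee, ankle) flexion at the peak-height frame,
the measured peak height, and clearing = peak height − step height; per
block, joint ranges of motion and total movement time.

## Within-trial exploration (recurrence analysis)

Covariance PCA (channels centered, not scaled; eigenvector sign fixed so
the hip-flexion loading is ≥ 0) compresses the 7 channels; the similarity
of first eigenvectors across blocks is their absolute dot product.

Three recurrence analyses per block:

* **PCA-aRQA** of the z-scored first-component scores, embedded with delay
  at the first local minimum of average mutual information (16-bin
  histogram estimator; a series whose lag-1 AMI is already at the
  shuffled-series bias level gets delay 1) and dimension from the Kennel
  false-nearest-neighbour rule (Rtol = 10, Atol = 2, OR of the criteria,
  threshold 1 %, cap 12). Theiler window = delay · dim.
* **cRQA** of knee vs hip flexion, each min–max scaled to [0, 1], embedded
  with the parameters selected on the knee series; no Theiler exclusion (a
  cross plot has no line of identity).
* **mdRQA** of the per-frame 7-vector, channels z-scored, no additional
  embedding ("embedding dimension and delay zero" is read as dimension
  multiplier 1, delay 0, since a literal dimension of 0 is undefined);
  Theiler window 1.

The recurrence threshold ε is 10 % of the maximum phase-space distance,
computed once per participant × analysis type and shared across that
participant's blocks: recurrence rate is itself an outcome, so ε must not
be re-tuned per block. Measures use lmin = 2 for diagonal and vertical
lines, entropy in bits, and all statistics exclude the Theiler band
(|i − j| ≤ w). These constants are not recoverable from the original
description and follow common recurrence-analysis practice; they are all
configuration-exposed, and the implementation is pinned to a naive
double-loop oracle by the test suite rather than to published figures.

For tractability the pipeline decimates the filtered series by a factor of
2 (60 Hz) before the recurrence analyses; a 10-movement block then yields
≈ 1400–1600 state vectors, and line structures at 6 Hz bandwidth are
unaffected.

## Between-trial exploration (task space)

The planar forward model maps hip and knee to heel height,
`heel_z = hip_z + thigh_l·sin(hip_a) + shank_l·sin(knee_a + hip_a)`, with
`hip_a` relative to the horizontal axis and `knee_a` relative to the
thigh. Recorded flexion angles bridge to model angles as
`hip_a = hip_flex − 90°` (thigh straight down at zero flexion) and
`knee_a = knee_flex` (extended knee continues the thigh line); the bridge
is configuration-overridable. Angles are carried in degrees externally and
radians inside trigonometry.

At the mean block configuration the height gradient
`g = [thigh·cos(hip_a) + shank·cos(knee_a + hip_a), shank·cos(knee_a + hip_a)]`
defines the orthogonal unit direction; its perpendicular (tangent to the
constant-height contour) is the equivalent direction. Both directions are
identical in flexion coordinates because the bridge is a rigid shift. The
centered scatter is projected on each direction; with an orthonormal basis
the two projected variances partition the total variance exactly.

The dispersion ellipse covering a fraction q of a bivariate normal has
area `π·χ²₂(q)·√det(Σ̂)` with q = 0.85 — the closed-form reading of an
"85 % of the data" ellipse from a covariance.

**Tolerance cost.** The task has no external target, so tolerance is
defined as robustness of the outcome to the observed scatter: t_cost = SD
of model heel height over the actual cloud minus the minimum of that SD
over rigid translations of the cloud on a ±40° grid at 0.5° steps around
its mean. It is non-negative by construction and 0 when the cloud already
sits at the most tolerant reachable location. The original tolerance-cost
variant is cited without parameters, so no numerical agreement with its
scale is claimed; the noise and covariation components of the full
tolerance–noise–covariation decomposition are out of scope.

## Trial-to-trial dynamics

Execution variables are the hip and knee flexion at peak height across the
50 movements of a condition; the outcome is the measured peak height.
Discontinuities are found per variable by binary segmentation: at each
step the split maximising the absolute Welch t between the two sides
(each ≥ 5 movements) is tested with a permutation p-value (199
permutations of the segment), recursing while p < α. Testing the maximal
statistic against a permutation null — rather than reading the Welch t off
the t distribution — is what keeps the false-positive rate of the search at
its nominal α despite the maximisation over split points; α is
Bonferroni-split across the execution variables, and indices found in
different variables within one movement are merged. Defaults: α = 0.05,
minimum segment 5, all configuration keys.

Segments between discontinuities are labelled by OLS slope t-tests against
movement index: *maintenance* (no execution trend, no outcome trend),
*covariation* (execution trend, stable outcome), *change* (execution trend
that alters the outcome). An outcome trend without any execution trend has
no execution change to report and falls back to maintenance. Segments
shorter than 3 movements are labelled maintenance with a warning. A
discontinuity is a *jump* when the mean of at least one execution variable
differs across the adjacent segments (Welch test at α). Jump chance is
reported both per block (share of blocks containing ≥ 1 jump) and per
discontinuity, since "a 50 % chance of jumps" admits both readings.

## Block-level inference

Each measure is summarised per participant × condition × block and fit
with a linear mixed model: fixed effects intercept, step-height condition
(numeric 1, 2), block within condition (numeric 1–5) and their
interaction; a random intercept per participant. Fixed-effect t statistics
use residual df = n − 4 — the convention that reproduces t(30) for the 34
analysable blocks of the study design — rather than Satterthwaite
approximations; the choice is documented and switchable. R² is computed
from fitted values conditional on the random effects. Missing blocks are
absent rows, never imputed. No multiple-testing correction is applied by
default (α = 0.05), matching the original analysis; a correction option
exists.

The per-block jump indicator is fit with a random-intercept logistic model
by variational Bayes (statsmodels `BinomialBayesMixedGLM`); posterior
means/SDs are reported as coefficients with normal tests, and a plain
logistic GLM fallback is flagged if the variational fit fails. A
degenerate indicator (all 0 or all 1) is reported as such. Extreme
coefficients are flagged as possible complete separation.

## Synthetic-data generator

The generator is the testbed: it emulates exactly the statistical
structure the analysis assumes and records the ground truth.

* **Cycle template.** The foot-lift profile is piecewise raised-cosine:
  dwell (2 %), rise to the main peak (23 %), lower onto the stepper
  (10 %), stepper contact at 55 % of peak lift (15 %), second rise to 80 %
  of peak lift (9 %), lowering (39 %), dwell (2 %) — two local maxima with
  the first the global peak. Joint angles follow a proportional path from
  standing to the movement's peak configuration (knee = coupling_gain ×
  hip, default 2.5; ankle = 0.6 × hip; the four secondary channels are
  small fixed fractions), obtained by inverting the measured-height map
  along the path, which is monotone for hip ≤ 90° and hip + knee ≤ 180°.
* **Measured foot height** is the forward model of the (noisy) hip/knee
  channels plus a marker offset scaled by the path parameter — zero at
  standing, exactly `toe_offset_m` at the peak. The planar model therefore
  underestimates measured peak height by exactly the offset (default
  0.105 m, the order of the reported systematic gap), while the standing
  foot height stays realistic.
* **Design defaults** are the study conditions: 4 participants, step
  heights 0.20 m and 0.32 m, 5 blocks × 10 movements per height, 120 Hz,
  cycle duration 2.4 ± 0.2 s, 1 s of quiet standing before the first
  movement. Per-height clearing targets 0.079 m and −0.017 m make the
  generator's ground-truth clearing means the reported ones (the foot
  marker peaks below the stepper top in the harder condition). The implied
  step-height increase (0.12 m) and peak-height increase (≈ 2 cm) follow.
* **Trial-to-trial process.** The peak-configuration mean is piecewise
  constant; each block has probability `jump_prob` (default 0.5) of one
  mean shift of `jump_size_deg` (default 6°, i.e. 3× the trial scatter) in
  a uniformly random direction of the hip–knee plane, at a position drawn
  away from the block edges; shifts persist into later blocks. Isotropic
  Gaussian scatter (2°) is added per movement, white Gaussian noise (0.5°)
  per frame and channel. Continuous drift is available behind a
  configuration flag for power studies but is off by default, matching the
  observed maintenance-plus-jumps pattern. Between-participant variation
  enters as a Gaussian offset of the clearing target (SD 1 cm). None of
  the scatter magnitudes are reported by the study; they are
  order-of-magnitude choices fixed once here.
* **Reproducibility.** One `numpy` generator seeded from the config drives
  everything; identical configs give bit-identical datasets.

What the generator does **not** emulate: marker drop-out and gap-filling,
inverse-kinematics artefacts, asymmetric or multi-modal trial scatter,
fatigue drift within blocks, coupling between cycle duration and
configuration, and any upper-body or contralateral-limb contribution to
foot height beyond the scalar marker offset. Tests passing on synthetic
data therefore validate the algorithms' contracts (segmentation counts,
recurrence measures, variance partitions, detector error rates), not the
physiological realism of any particular measured value.

## Numerical choices and degenerate inputs

* Filtering requires > 3 × order samples; cutoff must be below Nyquist.
* Strict inequalities in both findpeaks rules; flat peak plateaus report
  their centre sample.
* Constant series are rejected by the embedding-parameter selectors, the
  z-scorers and the unit-interval scaler (no information to normalise).
* Exact duplicate phase-space points (noiseless periodic series) are true
  neighbours in the FNN rule when the next coordinate also agrees.
* An empty diagonal-line set gives entropy 0 and LMAX 0; recurrence-rate
  denominators count only cells outside the Theiler band.
* Collinear scatter has ellipse area 0 (determinant clamped at 0);
  singular limb configurations (vanishing height gradient) are errors.
* A constant response yields zero slopes and undefined (NA) R²; mixed-model
  non-convergence is flagged on the result, never raised.
* Zero-variance Welch comparisons: t = 0 when means agree, ∞ otherwise.

## Problem sizes

The shipped test suite and the acceptance script run the full synthetic
design (40 blocks, 400 movements) with recurrence analysis at 60 Hz, 199
permutations in the changepoint test, 100–1000 Monte-Carlo replicates in
the detector/model-recovery checks, and a 100 000-sample calibration of
the coverage ellipse — sizes chosen so the complete run stays in the
tens-of-seconds range on a single CPU while keeping every Monte-Carlo
margin far from its decision boundary.

## Known limitations

* The recurrence constants (ε rule, lmin, Theiler, entropy base) follow
  field practice, not the original study's unstated values; absolute
  recurrence figures are not comparable to the original tables, only the
  structure of effects is.
* The tolerance-cost scale depends on the translation-grid definition and
  is not comparable to the originally reported coefficient magnitude.
* The binomial mixed model is variational, not marginal-likelihood; with 4
  participants its variance components are weakly identified (true of any
  estimator at this sample size).
* Jumps near a condition's first or last `min_segment` movements are
  structurally undetectable; the detected jump chance is accordingly a
  slight underestimate of the injected one.
* The changepoint permutation test assumes exchangeability under the null
  within a condition; autocorrelated trial-to-trial noise would inflate
  its false-positive rate.
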