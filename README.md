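# stepshape

Motor-exploration analysis of a Shaping stepping exercise for people with
chronic spinal cord injury — and for anyone studying how practice
restructures movement variability in a redundant task.

During Shaping (the intensive task practice of constraint-induced movement
therapy), a participant repeatedly places the foot of one leg on a stepper
whose height is titrated to keep the task challenging. From lower-limb
joint-angle recordings (7 channels: hip flexion/abduction/rotation, knee
flexion, ankle dorsiflexion/inversion/rotation at 120 Hz) plus the vertical
foot and hip positions, `stepshape` quantifies two complementary faces of
motor exploration:

**Within-trial exploration** — recurrence quantification of the joint-angle
dynamics of each 10-movement block:

* *PCA-aRQA*: auto-recurrence of the first principal-component score series
  of the 7 channels (covariance PCA), time-delay embedded with the delay at
  the first minimum of average mutual information and the dimension from
  false nearest neighbours;
* *cRQA*: cross-recurrence of knee vs hip flexion, each scaled to [0, 1];
* *mdRQA*: recurrence of the raw 7-dimensional joint state (no embedding).

From each recurrence plot `R[i,j] = 1{ ||x_i − x_j|| ≤ ε }` five measures
are reported: recurrence rate %REC, determinism %DET, Shannon entropy ENT
(bits) of the diagonal line-length distribution, the longest diagonal line
LMAX, and laminarity %LAM.

**Between-trial exploration** — the (hip, knee) flexion configuration at
peak foot height, movement by movement:

* a planar two-segment forward model of heel height,

  `heel_z = hip_z + thigh_l·sin(hip_a) + shank_l·sin(knee_a + hip_a)`,

  whose constant-height contour at the mean configuration defines the
  *equivalent* direction (execution changes that leave the outcome
  unchanged) and its normal the *orthogonal* direction;
* per-block dispersion: 85 %-coverage ellipse area
  `π·χ²₂(0.85)·√det(Σ)`, variance projected on each direction, and the TNC
  *tolerance cost* — how much the SD of heel height would drop if the whole
  configuration cloud were rigidly translated to the most error-tolerant
  spot;
* trial-to-trial dynamics: changepoint detection of mean discontinuities in
  the execution variables (binary segmentation, maximal Welch-t with a
  permutation p-value), maintenance/covariation/change labels for the
  segments between them, and jump/no-jump classification of each
  discontinuity.

Block-level effects of step height, practice block and their interaction
are estimated with random-intercept linear mixed models (t-tests on
residual df = n − 4) and a binomial mixed model for the per-block jump
indicator.

A synthetic-data generator (`stepshape.synthkin`) reproduces the study
design — 4 participants, 2 step heights × 5 blocks × 10 movements — with
known ground truth for every cycle boundary, peak configuration and
injected jump, so the entire pipeline is testable without any recordings.
The study's own motion-capture data are deposited at OSF
(https://osf.io/3n4tk/).

## Worked example

```bash
python analysis/01_simulate.py --seed 1   # write 40 synthetic recordings
python analysis/02_preprocess.py          # segment cycles, extract peaks
python analysis/03_rqa.py                 # PCA + three recurrence analyses
python analysis/04_taskspace.py           # dispersion + tolerance cost
python analysis/05_trialdyn.py            # discontinuities and jumps
python analysis/06_fit.py                 # mixed models over all measures
```

With seed 1 this prints, among other lines:

```
segmented 40 blocks, 400 movements; 0 blocks flagged by QC
mean clearing by step height (cm):
step_height_m
0.20    8.18
0.32   -2.47
mean loading similarity to each participant's first block: 0.983
planar model underestimates measured peak height by 10.47 cm on average
18 discontinuities (17 jumps) across 40 blocks
segment labels: {'maintenance': 23, 'covariation': 2, 'change': 1}
ground truth: jumps injected in 17 blocks; detector flagged 15 of them (recall 0.88)
```

Reading: clearing height (peak foot height minus step height) drops when
the stepper is raised, even though absolute peak height rises — the
participants operate at the edge of their capacity. The first principal
component barely changes across blocks (dot products ≈ 0.98), i.e. the
*coordination mode* is stable while its dynamics are explored. The planar
hip–knee model systematically underestimates measured peak height (here by
construction: the generator's marker offset). Between trials the
configurations show long maintenance stretches broken by discrete jumps —
exploration by occasional strategy shifts rather than continuous drift.

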