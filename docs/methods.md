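# Methods

## Signal model and preprocessing

Input is a uniformly sampled 50 Hz tri-axial acceleration stream in m/s²,
gravity included, from a phone worn in a hip bag in an arbitrary orientation.
Orientation is handled by rectification: taking |ax|, |ay|, |az| per axis
makes the stream exactly invariant to any combination of axis sign flips
(180° flips of the phone), which is the dominant orientation freedom in a
bag. Rectification is applied once at ingestion, before segmentation and all
feature computation; the one downstream quantity computed from the axes — the
resultant √(ax²+ay²+az²) — is sign-invariant anyway. Rectification does *not*
correct arbitrary rotations; residual small rotations are left for the
classifier to absorb (the synthetic generator deliberately injects them).

Upload chunks are joined before segmentation when consecutive files are
contiguous (gap ≤ 2 sample intervals); longer gaps split the stream, and
windows never span a split — interpolating across upload dropouts would
fabricate signal. Classification windows are 150 samples (3 s) advanced by 50
samples (1 s): one prediction per second, each window seeing 1 s of new data.
Edge remainders shorter than a window are dropped, not padded. Labeled
training windows inherit the majority label of the seconds they overlap, ties
going to the earliest second — transitions between activities are rare
relative to window count, so the tie-break is inconsequential but must be
deterministic.

## Features and relevance filtering

Each rectified axis of a window is summarized by a fixed catalog of 67
features in three families: distributional (moments, quantiles, RMS, energy),
temporal (successive differences, mean crossings, autocorrelation at lags
1–50, time-reversal asymmetry at lags 5 and 10, linear trend slope) and
spectral (the 25 DFT magnitude bins of the demeaned signal from 1/3 to
8.33 Hz, band-power fractions, spectral centroid and entropy, peak frequency
and magnitude). Three axes give 201 columns. The catalog is fixed and
versioned with the package rather than delegated to a feature library: the
exact census of features is not what matters — coverage of the three families
is — and a frozen catalog keeps feature names, counts and tests stable.
Non-finite values from degenerate windows (constant signal ⇒ undefined
moments/ratios) are replaced by 0 and logged.

Relevance filtering tests every (feature, class) pair with a two-sided
Mann–Whitney U test of the feature under the one-vs-rest class indicator,
pools all pairs, and applies Benjamini–Yekutieli FDR control at level 0.05.
BY rather than Benjamini–Hochberg because the feature columns are strongly
dependent (neighbouring DFT bins, quantiles of the same signal) and BY is
valid under arbitrary dependence; the cost is conservatism, which a
several-fold redundant catalog tolerates. A feature is kept if any of its
class tests is rejected. On pure-noise features with random labels the mean
selected fraction stays below the nominal level (property-tested).

## Classifier

A gradient-boosted decision-tree ensemble (LightGBM): 500 trees, depth ≤ 6,
63 leaves, learning rate 0.1, single-threaded and deterministic for a fixed
seed. These are ordinary GBDT settings for a few thousand rows × ~200
features; they are exposed in configuration, not tuned per dataset. Class
imbalance (the training mix is walking-dominated, roughly 20:1 against the
rarest transition class) is deliberately left unweighted by default so that
prevalence matches deployment; a reweighting flag exists. Training on fewer
than the seven canonical classes warns; a single class errors.

Generalization across people is measured with leave-one-subject-out
cross-validation. The relevance filter is re-fitted inside every fold —
selecting features on the full dataset before splitting would leak the
held-out subject's ranks into training. Reported are pooled per-window
accuracy and a row-normalized confusion matrix (each true-class row sums
to 1).

## Postprocessing

Order is fixed: the stationary rule first, then the reject option on the
seconds the model actually labels.

* **Stationary rule.** Sitting and standing are not classifier classes; a
  resting phone is detected directly. A second whose window has
  var(rx) < 0.1 (m/s²)² becomes `sitting_or_standing`, bypassing the model.
  The variance is computed on the rectified first axis; at rest every axis
  has near-zero variance, so the axis choice is immaterial there, and during
  movement the synthetic signal models keep var(rx) well above threshold.
  Sitting and standing cannot be distinguished under free orientation, hence
  the single merged label.
* **Reject option.** A prediction whose top probability is below δ (default
  0.5) becomes `unknown`: low confidence flags out-of-vocabulary activities
  and transition-straddling windows. The δ-sweep utility reports, over a
  threshold grid, accuracy on retained seconds and the retained fraction
  (non-increasing in δ by construction; property-tested against a brute-force
  count). With no seconds retained, accuracy is NaN with a warning.

## Cadence and cycle counting

Cadence per window is the dominant frequency of the resultant acceleration:
the window mean is removed (the ~9.81 m/s² gravity offset would otherwise
leak through the rectangular window's sidelobes into the whole low band),
the 150 samples are zero-padded to 512 (bin width ≈ 0.098 Hz versus the
native 1/3 Hz), and the magnitude peak is located in the physiological band
0.3–4.0 Hz with parabolic interpolation of the three bins around the peak to
remove quantization bias. A literal "maximal DFT amplitude" rule with no band
restriction would always return the DC/gravity term, so the band and DC
exclusion are required for the rule to mean anything. Peaks below an
amplitude floor of 0.1 m/s² return cadence 0 — a resting or aperiodic window
has no cycles; the default stationary noise level (σ = 0.05 m/s²) produces
spectral amplitudes an order of magnitude below the floor.

Cycle totals: every second bearing a cyclic label contributes its window's
cadence × 1 s. Sit/stand transitions are counted as maximal runs of
consecutive transition-labeled seconds, because a single ~1 s transition
appears in up to three overlapping windows and a raw window count would
triple-count it; the raw count is available behind a flag. The last two
seconds of a contiguous stream have no window starting at them and are not
counted — negligible at day scale.

## Load profiles and functional status

The packaged impulse table holds lab-measured average joint contact force
impulses ((N/BW)·s per cycle) for five template activities × two joints ×
three populations (healthy controls, end-stage hip OA, end-stage knee OA).
Point weights divide each impulse by the control walking impulse of the same
joint; the ratio is scale-invariant in the table's units. Scoring uses the
published 2-decimal weights — the point system as patients and therapists see
it — so the anchor identities hold exactly (10,000 walking strides = 100
points in every profile; 1,000 ascended stairs = 17.2 knee points under the
knee-OA profile); full-precision ratios remain available on the profile
object. Daily points are the weighted cycle sum divided by 100, anchoring
100 points ≡ 10,000 walking strides; each counted cycle is treated as one
anchor "step". The 100-point daily target is a default a therapist may
override per patient.

Mapping from classifier labels: `sit_to_stand` scores with the stand-up
template, `stand_to_sit` with sit-down. Jogging and cycling have no lab
impulse template and earn zero load points (configurable), while counting
fully toward activity-minute goals; `unknown` and `sitting_or_standing`
seconds carry no load. Both joints are always computed; reporting defaults to
the joint(s) implied by the diagnosis.

## Goals

A goal is (activity, minutes per session, sessions per week). Only time in
blocks of ≥ 10 minutes counts. Within a block, gaps of ≤ 5 s of `unknown` do
not break it (a single misclassified second should not void a 30-minute
bout) and the tolerated gap seconds are not themselves credited; any other
label, or a longer gap, ends the block. Qualifying minutes accumulate across
blocks within a day — the alternative reading (one continuous block per
session) was rejected as clinically harsher with no stated basis. A day is a
session when its qualifying minutes reach the goal duration; the goal is
achieved when sessions reach the weekly frequency. Evaluation is invariant to
day order.

## Synthetic data

The generator is an emulation designed so that each pipeline operator's
input assumptions hold measurably; it is not a biomechanical reconstruction.
Locomotor classes are a fundamental at the class cadence plus two harmonics
with class-specific amplitude, harmonic mix and per-axis weights (walking
1.9 Hz / 2.5 m/s²; ascending stairs slower with a strong second harmonic;
descending stairs faster and harder-impact with a strong third harmonic;
jogging 2.7 Hz / 6 m/s²; cycling a smooth 1.4 Hz nearly-pure tone at low
amplitude). Transitions are one smoothed transient per second whose time
asymmetry differs between standing up (fast rise) and sitting down (slow
rise). Stationary segments are gravity plus σ = 0.05 m/s² noise, comfortably
under the stationary-variance threshold. Subjects get reproducible cadence
(±5%) and amplitude (±8%) multipliers and a random orientation (sign flips —
removed exactly by rectification — plus rotations up to 15°, which are not).
Default per-activity durations scale a walking-dominated training mix down
20× to desk scale (280 s walking … 14 s per transition class per subject);
the class-imbalance ratios, not the absolute volumes, are the condition that
matters for the classifier.

What passing synthetic tests does **not** show: robustness to real gait
variability, OA-specific movement patterns, phone micro-movement in the bag,
or out-of-vocabulary activities. The LOSO harness reproduces the evaluation
protocol; accuracies on synthetic subjects (≈0.97 pooled at the default
conditions) say nothing about accuracy on real recordings.

## Problem sizes and numerical choices

Test-suite runs use 5 synthetic subjects (≈730 s each) for LOSO and a
balanced 5×7×30 s set for the label-permutation control — with a uniform
permuted truth multiset the expected fold accuracy is exactly 1/7 regardless
of the prediction distribution, which makes "chance level" well defined.
Cadence recovery is checked over 100 seeded trials at SNR 10 across
0.8–3.0 Hz (tolerance: one padded bin). All randomness flows from explicit
integer seeds through `numpy.random.SeedSequence`; reruns are byte-identical,
and every pipeline output embeds a hash of the producing configuration
(output location excluded — the same analysis written elsewhere is the same
analysis).

## Known limitations

* Rectification only neutralizes sign flips; large static rotations of the
  phone change per-axis feature distributions.
* Impulse templates are population averages from a lab protocol; individual
  joint loading can deviate substantially, and jogging/cycling loads are
  unmodeled (scored as zero).
* No temporal smoothing beyond the two rules: implausible label sequences
  (e.g. 3 s of cycling inside a walking bout) are not corrected.
* The stationary rule cannot separate sitting from standing, and slow
  low-amplitude movement (shuffling) may fall under the variance threshold.
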