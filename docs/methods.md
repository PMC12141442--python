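# Methods

This note records the models, conventions and numerical choices behind
`swimpose`, and what the synthetic-data tests do and do not establish
about recorded data.

## Coordinate and skeleton conventions

All analysis runs in millimetres in a right-handed frame (x right, y up).
Raster pose tables (y down) are flipped once at load with
`read_pose_table(..., y_down=True)`; nothing downstream ever re-flips.
Pixel input is converted to mm on load with the calibration
`mm_per_px = 0.0249` by default — a 6.38 mm well diameter (from the
0.32 cm² circular well area) spanning 256 px. The default frame rate is
160 frames/s; one 5-minute epoch is 48,000 frames.

The skeleton maps indices 0–7 to roles. The default order is
`snout, eye_left, eye_right, rostral_trunk, center, caudal_trunk,
mid_tail, caudal_fin`; only the snout, eyes, center and caudal fin carry
semantics, so alternative orderings can be supplied via `SkeletonSpec`.
The center of mass (COM) is the mean of the six non-eye midline points:
the laterally placed eyes would bias a full 8-point mean toward the head.
Missing or rejected frames are masked, never interpolated.

## Activity metric

A pixel counts toward the frame-pair activity iff its relative change
exceeds `t_rel = 0.1` **and** its absolute change exceeds `d_abs = 20`
(8-bit pixel units); both comparisons are strict. Pixels where the
two-frame sum is zero contribute nothing: their relative change is
undefined, but |Δ| = 0 already fails the absolute threshold, so no
epsilon or special case is needed. Arithmetic is done in float to avoid
unsigned-integer wraparound. Epoch totals below `exclusion_threshold =
20,000` pixels during the second treatment epoch flag the larva as
inactive (moribund) for exclusion from pose analysis. The stored metric
is linear counts; `log10(x + 1)` is applied only for display summaries
so zero-movement larvae stay finite.

## Cleaning cascade

Gates run in the fixed order **speed → well → COM**; a frame failing
several rules is attributed to the first gate that fires, and gates only
ever set `valid` frames invalid.

- **Speed gate** (`speed_max = 120 mm/s`): COM displacement from the
  previous *surviving* frame divided by the actual elapsed time across
  the gap. The gap-aware form means one removed frame cannot fabricate a
  doubled apparent speed at the next; the first valid frame is never
  removed. A consequence worth knowing: a transient one-frame excursion
  produces *two* anomalous displacements (out and back), and the gate
  removes the excursion frame on the way out — the return leg is then
  measured across the widened gap and survives.
- **Well gate**: the center key-point must lie within the closed disk of
  the well (`‖c − center‖ ≤ r`; the boundary itself is retained).
- **COM gate** (`com_factor = 0.7`): any key-point farther than
  0.7 × larval length from the frame COM invalidates the frame. Larval
  length defaults to "estimate": the median over valid frames of the
  midline polyline length snout → caudal fin, which is robust to a
  minority of corrupted frames.

**Denoising.** Each of the 16 coordinate features is smoothed
independently on each contiguous run of valid frames — no bridging
across removed frames, which would smear discontinuities into the
signal. The filter is discrete wavelet shrinkage with the sym4 wavelet:
soft thresholding of all detail levels at the universal threshold
σ√(2 ln n). The per-feature noise scale σ is the median absolute
deviation of the finest-level detail coefficients divided by 0.6745
(Gaussian consistency), optionally averaged across all tracks of one
plate acquisition (`average_sigma`). Soft thresholding was chosen over
hard for its continuity; the approximation band is untouched, so
constant segments pass through exactly and σ = 0 is the identity.
Segments shorter than the wavelet support are returned unchanged with a
warning. Running the cascade twice removes nothing new on the fixture
suite (idempotence), and removed + retained always equals the track
length (report conservation).

The 120 mm/s threshold is taken as configuration; `speed_histogram`
reproduces the cohort-level log-speed histogram from which such a cutoff
is read off as a diagnostic.

## Kinematics

- **Speed / distance**: gap-aware COM speed (mm/s, NaN on the first
  valid frame); cumulative distance in metres sums valid displacements.
- **Tail angle θ**: unsigned angle between the tail vector
  (center → caudal fin) and the *caudal extension* of the body axis
  (the snout → center direction). The extension — rather than the axis
  itself — is forced by the anchors: a straight larva reads 0°, a larva
  curled until the tail tip touches the snout reads 180°.
- **Heading change**: the heading vector points center → snout (where
  the animal faces). The per-frame change is the signed smallest
  rotation from the previous valid heading, counterclockwise-positive,
  wrapped to (−180°, 180°] with +180° kept at the boundary. Both signed
  values and magnitudes are available; distribution summaries use
  magnitudes.
- **Inter-eye distance**: Euclidean distance between the eye key-points,
  ≈ 0.2 mm for an upright larva and ≈ 0 when the larva lies on its side,
  making it a posture-loss proxy.

Degenerate geometry (zero-length tail or heading vectors) yields NaN for
that frame rather than an arbitrary angle. Epoch summaries use valid
frames only.

## Windowing, alignment, features

Windows are 60 frames (0.375 s) starting every `stride` frames
(default 15; the overlap degree is a free choice and configurable). Any
window containing a cleaned-out frame is dropped — interpolating through
rejected frames would launder exactly the artifacts cleaning removed.

Egocentric alignment computes **one** rigid transform from the first
frame of the window — rotate about the first frame's center key-point so
the heading maps to +y ("head up"), then translate that center to the
origin — and applies it unchanged to all 60 frames. Later frames are
deliberately *not* re-canonicalized: within-window motion is the signal.
The pivot choice (first-frame center key-point) is a convention; any
fixed pivot gives the same quotient under rigid motion. A window whose
first frame has a zero-length heading is rejected. Aligned windows
flatten in frame-major, key-point-major, (x, y) order to 960 features.

Normalization subtracts the per-feature training mean and divides by the
per-feature maximum absolute value *after* centering (zero divisors
replaced by 1); centering first makes the max-abs divisor a proper scale
rather than an offset-contaminated one. PCA retains the minimal number
of leading components whose cumulative explained variance reaches 95%.
Both transforms are fitted on the training split only and re-applied
verbatim to the test split. An all-identical training set is flagged
degenerate and projects to zero components.

## Classifiers and evaluation

The class-balanced split draws `round(0.1·n)` clips per class at random
for the test pool, trims every class's pool to the smallest pool size,
and returns the surplus to training — so test metrics are computed on
equal class support. "1000 iterations" maps to 1000 trees for the random
forest and a 1000-iteration optimizer cap for the SVC; k-NN has no
iteration parameter (none is faked). `tune_random_forest` searches a
deliberately small fixed grid (max_features × min_samples_leaf, 4
candidates) on an internal 80/20 validation split with 300 trees and
refits the winner with 1000 trees — a transparent stand-in for large
randomized sweeps.

Evaluation reports the confusion matrix (rows = true, columns =
predicted), per-class precision TP/(TP+FP) and recall TP/(TP+FN), their
macro averages, and an F1 computed literally from confusion-matrix sums:
diagonal over diagonal plus half the two symmetric off-diagonal sums.
For single-label multiclass matrices the two off-diagonal sums are equal
and the expression reduces algebraically to trace(M)/ΣM — overall
accuracy; both are reported, and the identity is verified numerically on
random matrices in the test suite. Classes absent from a test set have
undefined metrics and are flagged rather than zero-filled.

## Ethograms and statistics

Per-frame labels are the majority vote over all windows covering the
frame; ties resolve toward the *less severe* class in the fixed order
stationary < normal_swim < whirlpool < convulsion < posture_loss, so
overlap artifacts never inflate seizure calls. Frames covered by no
retained window are "unscored" and excluded from the class fractions,
which therefore always sum to 1.

Group comparisons use the Wilcoxon matched-pairs signed-rank test
(paired) or the two-sample t-test (unpaired), two-tailed, with
Shapiro–Wilk and Kolmogorov–Smirnov normality screens reported
alongside. Identical paired vectors return p = 1 by convention (the
signed-rank statistic is undefined on all-zero differences, and there is
no evidence of a shift).

## Synthetic-data generator

The generator exists so every stage has ground truth. The body model is
six midline points at 0.8 mm spacing (4 mm total — a typical larval
length; the length itself is a convention, not a measurement), with the
tail bend realized as progressive rotation of the caudal segments such
that the center → caudal-fin chord makes exactly the programmed angle
with the body axis, and the chord shortens linearly so a 180° bend puts
the tail tip at the snout. Eyes sit 0.3 mm caudal of the snout, ±0.1 mm
lateral (inter-eye 0.2 mm), collapsing to 0.01 mm apart under the
posture-loss flag. Every frame is recentered so the 6-point midline COM
follows the programmed trajectory exactly, which is what makes
programmed speeds recoverable to within raster/discretization error.

Class defaults: stationary — no translation; normal swim — 150 ms bursts
(peak 30 mm/s, sin² profile) alternating with 350 ms glides at 2 mm/s,
gentle heading wander, steering back toward the well center near the
wall; whirlpool — counterclockwise perimeter orbit, tangential speed
60 mm/s at radius 2.5 mm (angular rate integrated as v/r(t), radius
eased in over ≤ 0.25 s from the handoff position); convulsion — COM
oscillation along a slowly rotating axis with peak speed 110 mm/s at
10 Hz (amplitude = v/2πf, base point and amplitude eased in over 0.5 s
so concatenated epochs have no COM teleports), tail oscillation
amplitude 150° at 10 Hz, ±70° heading wobble; posture loss — near-static
with a constant 25° tail bend and collapsed eyes. Positional noise is
isotropic Gaussian, sd 0.02 mm — below typical pose-estimation error —
added to every key-point. Identical seeds give bitwise-identical tracks.

At 160 fps the measured chord speed of a sampled orbit underestimates
the arc speed by (ωΔt)²/24; at the default whirlpool rate this is ≈ 0.1%,
well inside the 1% recovery tolerance. The rendered frame stacks draw
the larva as tapering dark disks along the interpolated midline on a
bright background; rendering is deterministic, and pixel-change activity
grows with per-frame displacement until the moved body no longer
overlaps itself (beyond which raster quantization makes counts plateau,
not grow).

**What passing tests show — and don't.** The synthetic classes are
separable by construction (distinct speed regimes, tail amplitudes and
eye collapse, low noise), so near-perfect held-out classification on
generator data demonstrates that windowing, alignment, the feature
pipeline and the classifiers are wired correctly — not that real
annotated clips of these behaviors are this separable. The generator
also omits: pose-estimation error structure (correlated, key-point-
dependent, 55–130 µm scale), identity noise and occlusions, wall
interactions beyond simple steering, corkscrew/vertical components of
convulsions (2-D capture only), and between-animal variability.

## Problem sizes and determinism

Default suite and acceptance runs use desk-scale sizes chosen to
exercise every code path: 100 windows/class corpora (vs thousands of
annotated clips in a full study), 500-frame cleaning fixtures, 2–20 s
motifs, and one full 48,000-frame epoch for the windowing arithmetic.
All randomness flows from explicit seeds (NumPy `default_rng` /
scikit-learn `random_state`); the acceptance script derives every seed
from its `--seed` argument.

## Known limitations

- One larva per well is assumed; there is no cross-well identity logic.
- Denoising segments shorter than the wavelet support pass through
  unfiltered.
- The ethogram is a hard-vote summary; no probabilistic smoothing or
  duration priors are applied.
- Tail-beat frequency spectra and 3-D posture are out of scope.
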