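# Methods

## The decoding problem

Hand grasping engages ten measured joint degrees of freedom (MCP and IP of
the thumb; MCP and PIP of index, middle, ring and pinky). Rather than
decoding each joint independently from EEG, the pipeline assumes the
central nervous system controls grasping through a small set of *kinematic
synergies*: fixed spatiotemporal patterns of joint velocities. A movement
epoch is modeled as

    v(t) = sum_j c_j S_j(t)

where the rows S_j are the synergies and c_j scalar weights. Stacking one
flattened velocity epoch per trial into a matrix V (trials x concatenated
joint velocities), the singular value decomposition

    V = U Sigma S = C S

yields orthonormal synergy rows S and per-trial weights C = U Sigma. The
neural decoder is a multivariate linear regression C = X beta from EEG
spectral features X to weights, fitted on one group of subjects and
applied to held-out subjects whose kinematics are then reconstructed as
C_hat S. Accuracy is the Pearson correlation rho between recorded and
decoded joint-velocity traces (reported as a percentage); decoding error
is 1 - |rho|, so anti-correlated reconstructions count as zero error.

## Processing choices

- **Differentiation.** Angular velocity is the first-order forward
  difference of the recorded joint angles times the sampling rate
  (125 Hz). No smoothing is applied by default; a pre-filter can be added
  upstream by the caller.
- **Trial epochs.** 2 s from cue onset, half-open `[onset, onset+epoch)`,
  at each stream's native rate (250 kinematic samples, 512 EEG samples);
  the two streams are linked at the trial level only.
- **Row layout.** Epochs are flattened joint-major (all samples of joint
  1, then joint 2, ...) and the layout is carried on the matrix so synergy
  rows can be sliced back per joint.
- **SVD conventions.** The decomposition is applied to V directly (no
  mean-centering; a `center` flag exists for sensitivity analysis). Sign
  ambiguity is fixed by making each synergy row's largest-magnitude
  element positive, which makes repeated decompositions bitwise
  reproducible. Synergy count is the smallest leading set whose
  cumulative variance fraction reaches the threshold (default 0.85,
  inclusive comparison with a 1e-9 tolerance).
- **Weights.** Because the synergy rows are orthonormal, the least-squares
  weights are the plain projection C = V S^T.
- **EEG preprocessing.** Per channel: subtract the resting-segment mean,
  remove the linear trend, band-pass 0.1-56 Hz with a 4th-order
  Butterworth applied forward-backward (zero phase, so the 2 s epoch is
  not latency-distorted).
- **Spectral features.** 500 ms Hann-tapered periodogram windows sliding
  with 375 ms overlap across the post-cue epoch (13 windows at 256 Hz);
  the PSD is integrated over the analysis band with the trapezoid rule
  and divided by the band width (the raw integral is also available).
  Features are linear power by default; a log10 flag exists. Named bands:
  delta 0.1-4, theta 4-8, mu 8-12, beta 18-30, gamma 30-56 Hz; 12-18 Hz
  belongs to no named band and is covered only by the full-band set.
- **Reduction.** PCA across the pooled electrode-window features, fitted
  on training rows only; default rule keeps the smallest component count
  reaching 90% variance. The reducer records the exact training rows it
  was fitted on and the pipeline asserts that record against the fold's
  training set (leakage guard).
- **Regression.** One least-squares regression per grasp type (a pooled
  option exists), minimum-norm solution under rank deficiency with
  condition-number logging. The fit centers both features and weights on
  their training means and restores the weight mean at prediction — an
  intercept in effect. Per-task weight means are far from zero (they carry
  the grasp's mean movement pattern), so a no-intercept fit on centered
  features would systematically miss the dominant component; the bilinear
  no-intercept form remains available via `intercept=False`.
- **Cross-validation.** "10 folds with shuffled subjects" is implemented
  as 10 independent random half/half subject partitions (5/5 at ten
  subjects; floor/ceil for odd counts). A partition into ten disjoint
  folds is impossible with ten subjects and half/half splits. Synergies,
  reducer and regression are refitted per fold on training subjects only,
  and the selected synergy count is logged per fold.
- **Scoring.** rho is computed per joint over a trial's epoch samples,
  then averaged across joints, trials, tasks, subjects and folds; sd uses
  ddof=1. Accuracy is 100*mean(rho) in percent. Trials with a constant
  recorded or decoded trace have undefined rho, are flagged and excluded
  from aggregates rather than zeroed.

## Neural independency density

To map which scalp regions carry each synergy's encoding, features are
re-extracted from each electrode plus its montage neighbors (default
radius captures immediate neighbors on the grid), reduced, and regressed
per grasp task onto the synergy weights; the density is the sum of squared
regression coefficients over features and tasks,

    D_n(e) = sum_k sum_m beta_mk^2.

Three numerical choices matter here and are deliberate:

- The neighborhood features are reduced to a **fixed count** (default 10)
  of principal components rather than a variance fraction: overlapping
  windows make raw window features nearly collinear, and a
  variance-fraction rule would retain more components exactly where there
  is no signal, inflating the summed-beta^2 noise floor of empty bands
  and electrodes.
- The retained components are **whitened**, so the sampling noise of every
  coefficient has the same scale and densities are comparable across
  electrodes and bands.
- Features and weights are **centered within subject** inside each task
  before regression, so between-subject offsets (e.g. a subject's resting
  alpha amplitude) cannot masquerade as weight coding when few subjects
  are pooled.

Because the literature description is ambiguous about whether the scalp
maps use regression coefficients or correlation coefficients, both are
computed: D as above and an analogous R that sums squared feature-weight
Pearson correlations. Band-specific modulation maps repeat the
computation with features integrated over each named band.

## The synthetic cohort

No recordings are distributed with the protocol this package emulates, so
a generative module produces cohorts with known ground truth; it is
first-class, tested code. Defaults are the emulated study conditions: 10
subjects, 6 grasp types x 30 repetitions (180 trials per subject),
kinematics at 125 Hz, 32-channel EEG at 256 Hz, 2 s epochs, 4 s opening
rest and 1 s inter-trial interval.

**Kinematics.** Six orthonormal smooth random velocity curves form the
ground-truth synergies. Each trial draws weights from its grasp's
multivariate Gaussian (mean per grasp, diagonal within-grasp covariance);
velocities c^T S plus Gaussian noise are integrated to joint angles from a
flat-hand 0 deg start, with a constant-velocity return to rest between
trials. The grasp-mean matrix is drawn with orthogonal columns and
rescaled exactly, so each synergy carries a designed share of the signal
energy — (0.267, 0.189, 0.161, 0.139, 0.122, 0.122), split 70/30 between
across-grasp mean structure and within-grasp variation. With the default
velocity noise of 10 deg/s (about 10% of the total variance at the default
weight scale of 1500), the cohort's cumulative variance passes the 85%
selection threshold exactly at the sixth component (cum-5 ~ 0.79, cum-6 ~
0.90), which is what makes the selection rule testable.

**EEG.** Each electrode carries (i) a background of pink noise (2 uV rms),
white sensor noise (0.5 uV) and a 10 Hz resting rhythm (~3 uV) whose
amplitude drops to 40% for 0.5 s after each cue and rebounds to 150%
until ~1.6 s — post-stimulus desynchronization followed by
synchronization, a qualitative emulation only; and (ii) a 24 Hz carrier
(beta band) whose windowed band power equals baseline + coupling @ c +
noise. 24 Hz is an integer multiple of the 8 Hz window-step rate, so all
13 sliding windows see identical carrier samples, and the generator
calibrates carrier amplitudes against the package's own band-power
estimator — the encoded feature relation is therefore exact to numerical
precision when noise is off, giving the decoder a machine-precision
oracle. The coupling is an affine map (positive per-electrode baseline of
25 uV^2 plus a non-negative gain matrix) because weights are zero-mean and
a strictly linear map would demand negative band powers; band-power
targets are floored at 1 uV^2, with clipping negligible at the default
scales. Each synergy's coupling concentrates on a Gaussian patch (sd one
grid unit, truncated at two) around a distinct random center electrode,
so independency maps have recoverable structure. Feature noise (default
1.5 uV^2) is drawn once per trial and electrode and held constant across
the 13 windows — overlapping windows share samples, so per-window powers
cannot be set independently; the background supplies window-varying
noise.

The default noise levels follow an SNR budget chosen for a clean but
non-trivial regime: velocity SNR ~9:1 (so the rank-6 structure holds ~90%
of variance) and per-electrode feature SNR ~3:1 near coupling centers. At
these conditions the cross-subject pipeline reaches a mean accuracy in
the mid-80s percent — above, but on the same order as, the ~70% regime
the protocol emulates, since the synthetic cohort omits several hard
parts of real data (below).

**Randomness.** All draws flow from `numpy` `SeedSequence`s: the ground
truth from its own seed, each subject from the pair (ground-truth seed,
subject seed), and cohort subject seeds from the cohort seed. Identical
seeds reproduce cohorts bitwise. `true_weights` replays a subject's exact
grasp schedule and weight draw for parameter-recovery tests.

**What the generator does not emulate.** Volume conduction and realistic
forward-model topographies; eye-blink and muscle artifacts (the excluded
flag exists but nothing is auto-rejected); non-stationarities, electrode
drift and impedance changes; genuine inter-subject variability of the
synergy basis (a per-subject perturbation parameter exists, default 0,
since no magnitude is documented) or of the neural coupling. Passing
tests therefore show the pipeline's machinery is correct and leakage-free
— not that real EEG supports any particular accuracy.

## Degenerate inputs and tie-breaks

Empty velocity matrices, out-of-range bands, window widths not exceeding
the overlap, epochs extending past a recording and mismatched layouts all
raise with context. Cumulative-variance and PCA-count comparisons are
inclusive with a 1e-9 / 1e-12 tolerance. Rank-deficient regressions fall
back to minimum-norm solutions with a logged warning. Cohorts need at
least two subjects (a half/half split must exist).

## Problem sizes

Default study: 10 subjects x 180 trials; per fold, the velocity matrix is
900 x 2500 and the raw feature matrix 900 x 416 (32 electrodes x 13
windows). The full 10-fold study runs in about a minute on one CPU.
Unit-test fixtures use 2-3 subjects and 8 repetitions per grasp where the
full protocol is not itself under test.

## Known limitations

- Per-task regression requires the grasp label of a test trial (as does
  any per-task decoder); the pooled option drops that requirement at some
  accuracy cost.
- The independency density is a descriptive map; no significance testing
  is attached to it.
- EDF input is read-only (delimited text is the round-trippable format).
- The montage's eight intermediate electrode positions are synthetic
  stand-ins with invented 10-10 names and grid coordinates.
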