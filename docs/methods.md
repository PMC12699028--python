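# Methods

This note documents the models, conventions, numerical choices and known
limitations of the package. It is the reference for *why* each stage works
the way it does; the README shows *how* to run it.

## Signal processing and gait events

**Filtering.** Keypoint x/y trajectories are low-passed with a Butterworth
design (order 2, cutoff 10 Hz, at 50 Hz sampling) applied forward–backward
(`sosfiltfilt`). Zero-phase application was chosen because any phase lag
would bias heel-strike timing, which the whole stride segmentation hangs
on; the cost is an effective doubling of the filter order (the magnitude
response is squared). The confidence channel is never filtered. The
pipeline filters the *full* trajectory first and trims the 30 s
familiarization window afterwards, so filter edge transients fall in the
discarded window rather than in the analysis window.

**Missing keypoints.** A keypoint with confidence 0 is flagged missing.
Frames are retained; any stride whose signal touches a missing frame is
dropped during segmentation. No interpolation is performed — gap-filling
would fabricate kinematics exactly where the pose estimator failed.

**Heel-strike detection.** The per-frame Euclidean image-plane distance
between the left ankle and left hip peaks at terminal swing; initial
contact is the frame *after* the peak (offset +1 frame, 0.02 s at 50 Hz).
Peak picking uses two guards, both configurable:

* a minimum separation, defaulting to half the dominant period of the
  distance signal (estimated by periodogram), so at most one event per
  half-cycle;
* a minimum prominence of 25 % of the signal's peak-to-peak range, which
  rejects low-amplitude noise ripples near the mid-swing distance
  minimum. Without this guard, filtered keypoint noise occasionally
  produces a tiny local maximum in the distance valley that satisfies the
  separation rule and splits one stride into two, biasing mean stride
  time downward by ~0.03 s.

Plateau maxima (exactly equal consecutive samples) resolve
deterministically to the first frame of the plateau. Events whose offset
lands outside the trial are discarded. "Distance" is read literally as the
Euclidean distance, not a single-axis projection; detection is therefore
invariant to rigid translation, uniform scaling and rotation of the
keypoint coordinates.

**GRF events.** When a vertical ground-reaction-force trace is available
it serves as an independent event oracle: rising-edge crossings of 20 N
with a 0.5 s debounce, converted to keypoint frame indices. 20 N is the
common force-plate contact convention. Treadmill belt-crossover artifacts
are not corrected — the keypoint-based detector is the primary method
precisely because overstepping makes force-based segmentation unreliable.

**Segmentation.** Stride k spans event pair [e_k, e_{k+1}]; the signal is
linearly interpolated onto 101 equally spaced nodes of normalized time
(0–100 % of the gait cycle). Strides with durations outside 0.4–2.5 s
(configurable) are treated as detection glitches, dropped and logged.

## Joint-angle conventions

All angles are planar, computed in image coordinates (y down) for the left
side, from segment vectors between keypoints (trunk: hip→shoulder; thigh:
hip→knee; shank: knee→ankle; upper arm: shoulder→elbow; forearm:
elbow→wrist; whole arm: shoulder→wrist). Segment inclinations are measured
from the vertical, positive toward the facing direction (`forward`,
'+x' or '-x', recorded in the output metadata):

* hip flexion = incl(thigh) − incl(trunk); 0° with thigh aligned under
  the trunk, flexion (thigh forward) positive;
* knee flexion = incl(thigh) − incl(shank); 0° at a straight leg,
  flexion positive;
* shoulder flexion = incl(upper arm) − incl(trunk);
* elbow flexion = 180° − interior elbow angle (0° fully extended, ≥ 0 by
  construction);
* arm swing = inclination of the whole-arm vector from the downward
  vertical, forward positive.

These are fixed conventions; any alternative convention is a documented
sign/offset transform away. Sanity bands (knee and elbow flexion within
[−20°, 180°]) catch gross convention or data errors at container
construction. Degenerate frames (coincident keypoints) yield NaN and drop
the enclosing stride.

The non-functional-arm exclusion (scratching, fixing hair) removes a
stride from *all* arm signals when its minimal interior elbow angle falls
below 80°; leg signals are untouched. The exclusion runs before cv/ROM
computation. A threshold of 0 disables it. If every stride is excluded
the participant's arm features are reported missing rather than invented.

## Discrete features

The variability index is

    cv = sqrt( (1/N) Σ_i σ_i² ) / ( (1/N) Σ_i |X_i| ),  N = 101,

with σ_i and X_i the across-stride standard deviation and mean at node i.
The standard deviation uses the sample convention (ddof = 1); with only a
handful of strides the population convention would understate variability.
Nodes where all strides coincide exactly are assigned σ_i = 0 directly, so
identical strides give cv = 0 without floating-point residue. cv is
invariant to positive rescaling and deliberately sensitive to additive
offsets (the denominator is the mean absolute level). Range of motion is
the per-stride max − min, averaged over strides. Features are averaged
over the two bouts per participant; a missing bout is an error unless
explicitly allowed.

## Statistics

**ANOVA.** `MixedAnova` (one between-, one within-subject factor) and
`RepeatedMeasuresAnova` enforce balanced designs (every subject × level
cell filled exactly once; no imputation) and delegate the sums-of-squares
computation to pingouin; the test suite checks the fitted F, df and
partial η² against an independent projection-based decomposition to
1e-10. Partial η² is SS_effect/(SS_effect + SS_error) with the error term
matched per effect. Greenhouse–Geisser ε and the corrected p-value are
reported alongside the uncorrected one for within effects (sphericity is
rarely tenable for six ordered cortisol samples); at n = 2 subjects the
Mauchly/ε machinery is undefined and the uncorrected table is returned.
A zero within-effect SS is reported as F = 0, p = 1 (the effect is exactly
null); zero *error* variance with a nonzero effect raises a
degenerate-model error.

**Gated pairwise tests.** Shapiro–Wilk at α = 0.05 on each sample (on the
differences when paired) selects t-test vs. Wilcoxon. The two-sample t
defaults to Welch's form (no equal-variance assumption; a pooled-variance
flag exists). The non-parametric branch uses the signed-rank test (paired)
or rank-sum test (independent). Constant samples, where Shapiro is
undefined, take the parametric branch with a note — the t-test handles
them deterministically. Bonferroni correction is applied within feature
groups (cortisol, PANAS, SSSQ, discrete gait features), p_bonf =
min(1, m·p). Hedges' g = J·(mean_a − mean_b)/s_pooled with
J = 1 − 3/(4(n_a+n_b−2) − 1) accompanies parametric comparisons. The
empirical size of the gated procedure is verified by Monte Carlo (2000
replicates) under both normal and lognormal nulls.

**SPM{t}.** Each participant contributes one 101-node mean waveform per
signal. The node-wise two-sample t statistic (pooled variance,
ν = n_A + n_B − 2) forms a 1D random field. Field smoothness (FWHM, in
nodes) is estimated from the gradient variance of the unit-normalized
model residuals. The two-sided family-wise critical threshold solves

    α/2 = P(T_ν > t*) + (L/W) · sqrt(4 ln 2)/(2π) · (1 + t*²/ν)^(−(ν−1)/2)

(the expected-Euler-characteristic approximation for a smooth t field;
L = 100 node intervals, W = FWHM), by Brent root finding with an
adaptively widened bracket (heavy t tails at tiny ν push t* beyond 100).
Suprathreshold clusters are the maximal runs with |t| > t*, reported in
percent-of-stride coordinates with a direction sign. Zero-variance nodes
are excluded with a warning. A permutation threshold — the (1−α) quantile
of the max-|t| null over group relabellings, enumerated exactly when the
total count is ≤ 20,000 and sampled (default 10,000) otherwise — provides
a distribution-free cross-check; on smooth fields it agrees with the RFT
threshold within a few percent, and a 5000-replicate null simulation puts
the empirical family-wise error at 0.050 for α = 0.05 (n = 15/group,
FWHM ≈ 15 nodes). SPM is applied to the lower-limb signals (hip and knee
flexion), where time-resolved analysis is warranted; upper-limb
differences are captured by the discrete features.

## Synthetic data

The generator produces inputs whose ground truth is recorded losslessly,
so recovery can be asserted exactly.

**Walker.** A planar chain (trunk, thigh, shank, upper arm, forearm, plus
a rigid head) is driven by truncated-Fourier joint-angle waveforms over
the stride cycle; defaults are smooth normative-shaped curves (hip
8° ± 22° peaking at heel strike; knee near-extended at contact with a
~57° swing peak; arms antiphase with the legs). The hip oscillates
vertically at stride frequency; all other keypoints follow by forward
kinematics, which makes the angle-recovery inverse exact by construction.
The knee waveform is validated against hyperextension (< −10° raises).
True heel strikes are the frames of maximum ankle–hip distance, recorded
*before* the +1 frame detection offset; peaks within half a cycle of the
trial edges are not part of the truth (truncated edge cycles have no
well-defined maximum), so detector and truth agree exactly over the truth
span on noiseless data. Gaussian pixel noise (default 2 px, the typical
magnitude of pose-estimator jitter) and constant per-keypoint
clothing-bias offsets are added *after* the truth is recorded. A constant
(not time-varying) bias is the simplest mechanism that reproduces a
systematic angle shift; a vertical 8 px offset on the knee keypoint
shifts late-stance knee flexion by ~1.5° while moving late-stance hip
flexion by < 0.5°, isolating the clothing-artifact mechanism. Vertical
GRF is synthesized as a double-bump profile (1.1 sin πs + 0.3 sin 3πs,
clipped at 0, body weight 700 N) active for 60 % of each cycle — the
standard stance fraction — starting at each true heel strike, at 1000 Hz.

**Cortisol.** The response curve is baseline + A·g(t − onset) with g a
gamma-shaped pulse of unit peak at `peak_delay` minutes (default within
the physiological 15–20 min window) and decay scale 10 min, evaluated at
the six protocol sample times, with optional multiplicative lognormal
noise and clipping at 0. The amplitude A is *signed* in the cohort
generator: negative draws model the afternoon circadian decline below
baseline that real protocols show after the walking task.

**Cohort.** The default cohort mirrors the study conditions end to end:
two groups; two 240 s bouts per participant at 50 Hz with stride times
drawn per participant (slow bout 1.25 ± 0.07 s for 0.9 m/s, fast
1.10 ± 0.07 s for 1.2 m/s); between-participant kinematic individuality
as waveform mean/amplitude offsets (hip ±2°/±1.5°, knee ±2°/±2.5°, elbow
±1.5°, draws clipped at 2 sd to respect the hyperextension guard) shared
across bouts; 2 px keypoint noise in both groups plus the knee
clothing bias in the OMC group only. Cortisol baselines are lognormal
(median 2.4 nmol/L); amplitudes are N(1.0, 2.25) nmol/L for the OMC group
and N(0.3, 0.85) for controls — the spreads mirror the response
variability of marker-based vs. everyday-clothing conditions — with
per-participant onset jitter (sd 3 min) and peak delay uniform in
15–20 min; the OMC sampling schedule is later (marker application
precedes walking). Questionnaire items are drawn by rounding normal
variates (item sd 0.9, participant random intercept sd 0.3) around
subscale means; the OMC group receives a Q-marker timepoint with negative
affect raised and positive affect lowered by 0.7 scale points
(≈ g 1.7 at the between-participant spread used), and both groups drift
slightly toward lower distress/self-evaluation at Q-post. The control
group has no Q-marker, as in the protocol. Identical seeds give
bit-identical datasets.

**What the generator does not emulate.** Soft-tissue and clothing motion
are reduced to white noise plus a constant offset; pose-estimator
failures are modeled only through the confidence-0 mechanism, not as
outlier swaps between left/right limbs; gait is strictly periodic apart
from waveform jitter (no fatigue drift, no step-to-step timing
variability within a trial); cortisol follows a single smooth pulse (no
pulsatile secretion); questionnaire items are conditionally independent
given the subscale mean. Passing recovery tests therefore demonstrates
correctness of the *computational chain*, not robustness to every failure
mode of real video data.

## Problem sizes

Unit and acceptance tests use trials of 10–14 s (≥ 10 cycles) for walker
recovery, 45–120 s trials and 2–10 participants per group for pipeline
runs, 1000–2000 Monte-Carlo replicates for calibration checks, and the
acceptance script's cohort analysis runs the full study geometry
(20 per group, two 240 s bouts, 30 s trim). These sizes put every
statistic well past its asymptotic regime while keeping a full run in
tens of seconds.

## Known limitations

* The RFT threshold uses the standard EC-density approximation; for very
  rough fields (FWHM ≲ 5 nodes) or tiny groups (ν ≲ 4) it becomes
  conservative and the permutation threshold is the better reference
  (both are always computable).
* The elbow-flexion convention is unsigned (interior-angle deficit), so
  elbow hyperextension is indistinguishable from flexion; irrelevant for
  walking but wrong for tasks with locked-back elbows.
* Heel-strike detection assumes roughly periodic walking; it is not a
  general event detector for pathological or stop-and-go gait.
* Scoring keys ship with sensible defaults (standard PANAS item split;
  SSSQ as six 4-item blocks) but published translations order items
  differently — for real instruments the key YAML must be supplied.
* The mixed ANOVA requires complete, balanced data; participants missing
  a timepoint or sample must be excluded upstream, matching the study's
  own exclusion practice.
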