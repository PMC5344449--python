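# Methods

`nirstroop` implements a complete group analysis for a two-task conflict
(Stroop) experiment measured with continuous-wave fNIRS, together with a
synthetic-data generator that makes every stage testable against planted
ground truth. This note documents the models, the defaults and why they
were chosen, and what the synthetic validation does and does not show.

## Study design emulated by the generator

Each subject performs two runs: a gesture task (affirmative/negative
gestures paired with spoken "yes"/"no") and a color task (the words
"red"/"green" in congruent or incongruent font color). A run consists of
twelve 15 s task blocks alternating with 15 s rest (360 s total). Blocks
hold four trials at a 3.75 s inter-stimulus interval; half the blocks are
congruent-dominant and half incongruent-dominant, and each block embeds
exactly one oddball trial of the opposite congruency at a uniformly random
slot (48 trials per run). Gesture trials carry randomized nuisance
attributes (actor gender, gesture type) that have no hemodynamic effect by
default.

The montage has 30 emitters and 29 detectors at 3 cm nominal spacing,
giving 98 measurement channels whose locations are the emitter-detector
scalp midpoints. The default layout is a 4 x 15 checkerboard band wrapped
around a head of radius 85 mm (one inferior posterior-left detector slot
unpopulated), covering frontal, temporal and parietal cortex bilaterally
with no occipital coverage. Optical intensities are sampled every 27 ms at
780, 805 and 830 nm; 805 nm sits near the hemoglobin isosbestic point.

## Forward model

Condition regressors (per-trial boxcars, default duration 1.5 s) are
convolved with a canonical double-gamma HRF (peak 6 s, undershoot 16 s,
peak:undershoot 6:1, unit peak) and scaled by per-channel amplitudes in
µM-equivalent units. On top of the evoked signal the generator adds
global systemic oscillations — cardiac (~1 Hz), respiratory (~0.25 Hz) and
Mayer waves (~0.1 Hz) — shared across channels with per-channel gains
drawn around 1 (SD 0.1), per-channel slow drift, and white noise
(default SD 1 per sample). Deoxyhemoglobin mirrors the noiseless
oxyhemoglobin signal scaled by −1/3 (configurable; empirically HbR
responses are smaller and inverted) plus independent noise. Optical
densities follow from the modified Beer-Lambert law

    ΔOD(λ, t) = [ε_HbO(λ) ΔHbO(t) + ε_HbR(λ) ΔHbR(t)] · L,

with extinction coefficients interpolated from the Prahl/Gratzer
compilation and the unknown differential pathlength folded into the
reported units (relative concentrations only). Intensities are
I = I₀·10^(−ΔOD). Per-subject probe placement scatter is modeled as 2 mm
Gaussian jitter on optodes and fiducials.

The default planted activation mirrors the loci the analysis is meant to
detect: a gesture-task effect in the five channels nearest MNI
(70, −32, 14) (right temporal) and the two nearest (−54, 24, 28) (left
DLPFC), and an incongruency effect in the two channels nearest
(50, 25, 40) (right DLPFC), each 1 noise-SD strong.

Reaction times are lognormal per trial, parameterized to hit a requested
mean and SD exactly; incongruent trials add a congruency delta to the mean
(defaults: gesture 1365 + 40 ms, color 658 + 106 ms), each subject carries
a normal offset shared by both congruencies (between-subject SD 900/800 ms,
chosen so the group SEM lands near the magnitude such studies report), and
responses are correct with probability 0.982/0.987.

## Preprocessing

Fixed order: optical density → MBLL inversion → dead-channel QC → wavelet
detrend → low-pass → PCA spatial filter → 10-fold downsampling.

- **Dead channels**: a channel is excluded iff the RMS of its raw trace
  exceeds 10× the mean RMS across channels.
- **Wavelet detrend**: `db4` decomposition with symmetric boundary
  handling; the approximation band (below ~0.01 Hz at the default depth)
  is zeroed, removing drift while leaving the 1/30 Hz task cycle intact.
- **Low-pass**: zero-phase (forward-backward) 4th-order Butterworth at
  0.1 Hz. Zero-phase filtering avoids biasing HRF latency.
- **PCA spatial filter**: spatial principal components are computed from
  the channel covariance; components whose spatial-uniformity score
  |mean(loading)|·√C exceeds 0.7 are projected out (default). This
  targets genuinely global physiology. A blind top-k mode exists but is
  not the default: after the low-pass has removed cardiac and respiratory
  power, the leading component is frequently the spatially coherent task
  response itself, and projecting it out destroys the effect of interest.
- **Downsampling**: every 10th sample after the anti-alias low-pass
  (27 ms → 270 ms).
- **QC metric**: per-channel RMS of the residual after regressing on the
  HRF design (`hrf_residual_rms`) is reported, not used as a transform.

Deoxyhemoglobin is the default analysis chromophore (less contaminated by
systemic artifacts); because HbR falls during activation, the series is
negated before the GLM so reported betas and t values are
activation-positive for either chromophore.

## First-level GLM and contrasts

Per channel, ordinary least squares of the preprocessed series on the
HRF-convolved design (one regressor per task × congruency condition plus a
constant; oddball trials count toward their own congruency). Contrasts are
formed per run and summed across a subject's runs: incongruent > congruent
combined over tasks (I>C) and gesture > color combined over congruencies
(G>C). A gesture-only activation of amplitude a appears as ≈2a under G>C
because both gesture congruency columns enter with weight +1.

## Group inference

Subjects are registered to a template head by a least-squares similarity
transform (Umeyama) on the five digitized landmarks (nasion, inion, Cz,
T3, T4); channel contrasts are then aligned to the component-wise median
channel coordinates by inverse-squared-distance (Shepard) interpolation
over each subject's 4 nearest channels.

Two complementary tests are run on the aligned contrasts:

1. **Channel-wise**: one-sample, one-tailed t per channel (df = n−1),
   flagged at p < 0.05. This keeps the number of comparisons at 98.
2. **Voxel-wise**: contrasts are interpolated onto a 4 mm isotropic MNI
   grid with a normalized Gaussian kernel (FWHM 15 mm) and a one-sample,
   one-tailed t-map is computed per voxel. Suprathreshold voxels
   (p < 0.001) are grouped into 18-connected clusters; clusters of ≥ 70
   voxels meet the extent criterion.

The grid mask is the intersection of channel support (within 20 mm of a
channel) and a cortical shell 5–25 mm below the scalp surface, where the
scalp is the circle fitted to the optode footprint. The shell reflects
fNIRS physics — the technique samples superficial cortex, not the scalp or
deep structures — and it is what calibrates the cluster criterion: without
it the support mask is a 40 mm thick slab in which almost any voxel-level
exceedance spans 70 voxels of depth, and the cluster correction loses its
bite.

**Cluster calibration.** The familywise false-positive proportion of
"any cluster of ≥ k voxels at voxel p" is estimated by sign-flip Monte
Carlo: each permutation independently multiplies every subject's volume by
±1, recomputes the group t-map, and records the maximal suprathreshold
cluster per threshold. The procedure is exact under a symmetric null.
Under the default pure-null simulation (30 subjects of iid standard-normal
channel contrasts, 1000 permutations), the (≥70 voxels, p < 0.001) cell
lands near 0.05, the loose (≥10, p < 0.05) cell saturates at 1, and the
grid is monotone in both directions. Sign flips are drawn independently
per subject; computation uses the identity that sign flips leave the
per-subject sum of squares unchanged, so each permutation costs one
matrix-vector product. An exhaustive mode enumerates all 2ⁿ assignments
for small n and is used as the oracle for the Monte Carlo.

**Dual criterion.** A finding is *significant* only if its cluster passes
the voxel-wise criterion (p < 0.001, ≥ 70 voxels) AND at least one flagged
channel lies within 20 mm of the cluster; a cluster backed by a flagged
channel but failing the extent criterion is reported as *active*.

## Behavioral analysis

Gesture stimulus onsets are the median of independent rater annotations
per video (mean of the two central values with four raters). RTs aggregate
subject-first: per-subject condition means, then group mean and SEM
(SD/√n) across subjects. Congruency and task comparisons are one-tailed
paired t-tests, t = mean(d)/(SD(d)/√n), df = n−1. Error trials are kept in
RT summaries by default (a flag excludes them); accuracy is percent
correct per task.

## Numerical choices and degenerate inputs

- OD uses the log₁₀ convention; round trips are self-consistent to 1e−12.
- MBLL inversion is the pseudoinverse solution; exact for noiseless
  forward data (round-trip error < 1e−9).
- Zero-variance voxels in a group t-map are NaN-masked and excluded from
  clustering; channels with per-subject gaps use per-channel n.
- Nonpositive intensities cannot be log-transformed; such samples are
  zeroed and flagged for QC rather than aborting the run.
- Similarity registration refuses coplanar landmark sets (rotation
  under-determined).
- The fine grid for HRF convolution is min(frame step, 0.1 s), keeping
  designs consistent across sampling rates to ~1e−6.

## Problem sizes used by the validation suite

The shipped tests and drivers run the full cohort at its native size
(31 subjects, 98 channels, 13 333 samples/run, two runs) for the
end-to-end checks, 1000 permutations for the null calibration, 100
simulation seeds for GLM recovery (at the post-downsampling rate), and
200 replicate seeds for the behavioral Monte Carlo oracles. Null
dual-criterion runs operate on the pure-null channel-contrast mode rather
than regenerating full raw cohorts, which is the same group-stage
computation at a fraction of the cost.

## What the synthetic validation does not show

The generator's noise is white and Gaussian with stationary systemic
oscillations and near-uniform global gains; real fNIRS data show
heteroscedastic, autocorrelated noise, motion artifacts (not modeled — no
spline/TDDR correction is included), scalp-blood-flow transients, and
optode-coupling changes. Subjects share identical planted amplitudes, so
between-subject effect variability comes only from estimation noise and
group t values on planted effects are far larger than any real study
would produce; power numbers here are upper bounds. Channel-to-cortex
geometry uses midpoints on an idealized head rather than photon-transport
sensitivity profiles, and no anatomical atlas lookup is included — peak
coordinates are interpretable only relative to the synthetic montage.
Passing tests demonstrate the correctness and calibration of the
*procedures*, not the physiological realism of the simulated data.

## Known limitations

- The median-coordinate registration approximates the named nonlinear
  interpolation idea with Shepard weighting; with dense montages and
  small placement jitter the choice is not critical (a 1 mm displacement
  changes aligned values by < 10% of a unit contrast).
- The cluster calibration depends on the montage and kernel via the
  field's smoothness; the printed operating point holds for the default
  geometry and FWHM 15 mm and should be re-run (script 05) after any
  geometry change.
- SNIRF support covers the single-block continuous-wave subset this
  pipeline produces; it is not a general SNIRF validator.
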