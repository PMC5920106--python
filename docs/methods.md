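# Methods

`alphap1` implements a complete analysis chain for a two-condition visual
EEG experiment in which each trial presents a *cue* image followed, 1017 ms
later, by a *target* image, and each trial belongs to a *meaning-trained*
or *meaning-untrained* condition. The scientific questions the chain
answers are: (i) is pre-target alpha-band (8–14 Hz) power elevated on
trained trials, and over which time interval and hemisphere; (ii) is the
target-evoked P1 component larger on trained trials; and (iii) do the
per-subject alpha and P1 condition effects covary across subjects.

## Pipeline

Per subject, epoched data (trials × channels × samples at 500 Hz, µV)
pass through:

1. **Amplitude rejection.** Any epoch with a sample strictly exceeding
   ±75 µV at any electrode is discarded. Strict inequality is deliberate:
   an epoch that exactly touches the threshold survives. The rejection log
   (per-epoch peak amplitude and decision) is persisted.
2. **Optional spherical-spline interpolation** of listed bad channels.
3. **Surface Laplacian** (current source density) via spherical splines:
   the spline kernel is the Legendre series
   `g(x) = (1/4π) Σ_{n≥1} (2n+1)/(n(n+1))^m P_n(x)` with stiffness `m = 4`,
   truncated at 50 terms, ridge-stabilized with λ = 1e-5; the Laplacian
   kernel multiplies each term by `n(n+1)`, so a degree-l spherical-harmonic
   potential maps to ≈ `l(l+1)` times itself (source-positive CSD
   orientation). The head is the unit sphere, so CSD values are in
   consistent arbitrary units; every downstream statistic is a condition
   contrast and therefore invariant to this overall scale. The unit tag
   flips µV → µV/cm² exactly once; stages guard on it, so running
   rejection after the Laplacian (or the Laplacian twice) raises.
4. **Two analysis branches.** The ERP branch is band-pass filtered
   (0.05–25 Hz, first-order Butterworth, applied forward–backward so the
   effective response is |H(f)|² with zero phase — a single causal pass
   would delay the P1 peak) and baselined by subtracting the mean of the
   200 ms before target onset. The spectral branch decomposes the
   *unfiltered* CSD signal with Morlet wavelets.

### P1 quantification

The grand-average waveform (all subjects, both conditions, both
occipito-parietal ROIs — left {PO3, P3, P7, P9, O1}, right {PO4, P4, P8,
P10, O2}) defines one condition-neutral P1 peak latency in 70–150 ms
post-target (ties break earlier; a flat waveform warns and uses the window
midpoint). Per subject × condition × hemisphere, P1 amplitude is the mean
of the condition-averaged ROI waveform over a 30 ms window centred on that
peak. Single-trial peaks are the largest strict local maximum (greater than
both neighbours; window endpoints ineligible) of the ROI-averaged trial
waveform in 70–150 ms; trials without one are flagged undetected rather
than erroring. Note one discrete-sampling consequence: a noise-free
symmetric peak lying exactly between two samples produces a two-sample
plateau and counts as undetected; real data are never degenerate in this
way.

### Time–frequency analysis

Morlet family: 3–50 Hz in 1.6 Hz steps (30 centres, 3.0 … 49.4 Hz), cycle
count affine in list position from 3 to 10, `σ_t = cycles/(2πf)`, kernels
truncated where the Gaussian envelope < 1e-4 of max, odd length,
unit-energy normalized (any fixed normalization cancels in percent change).
Convolution is FFT-based linear convolution; equivalence with direct
time-domain convolution to 1e-10 relative is asserted by test, and the
working precision is selectable (float64 default; the pipeline uses
float32 for large simulation studies, where power only enters window means
and rank statistics). Power = |convolution|², converted to percent signal
change against the mean raw power in a −400…−100 ms pre-cue window pooled
over **all trials of both conditions** (a common baseline preserves the
between-condition ordering of raw power at every time point; per-condition
baselining is available behind a flag). Samples within half a kernel
length of an epoch edge are flagged, and windowed reductions refuse
edge-contaminated windows. The alpha band is the closed interval
[8, 14] Hz, which on this schedule contains the centres {9.4, 11.0, 12.6}.
Band time courses average those centres over an ROI's channels.

### Statistics

*Cluster-corrected permutation test* (paired, per hemisphere, on the
−500…0 ms pre-target band time course): per-sample paired t; the
cluster-forming threshold is the two-tailed t critical value at α = 0.05
with n−1 df (positive and negative runs form separate clusters); the
cluster statistic is run **length** in samples. The null permutes by
independently sign-flipping each subject's whole difference course; the
observed labeling is included in the null so p > 0. When 2ⁿ ≤ n_perm all
sign patterns are enumerated exactly (p-values are then multiples of 2⁻ⁿ);
a `method` switch forces Monte-Carlo or exact. A cluster is significant
when its size strictly exceeds the 95th percentile (linear-interpolation
quantile) of the null max-run distribution.

*Paired t* is classical, with a 95% CI of the mean difference. A constant
non-zero difference vector is returned as the limit (t = ±∞, p = 0, point
CI at the shift); identically zero differences raise, since they carry no
information.

*2×2 repeated-measures ANOVA* (condition × hemisphere) uses the classical
within-subject sum-of-squares decomposition, each effect tested against
its own effect-by-subject interaction. For 2-level factors each F equals
the squared paired t on the corresponding contrast — asserted to 1e-8 in
the tests, and cross-checked against an independent implementation
(pingouin).

*Across-subject coupling*: Spearman rho (mid-ranks) between per-subject
alpha modulation (trained − untrained pre-target band power) and P1
modulation (trained − untrained window amplitude), per hemisphere, with a
20,000-draw subject-resampling percentile bootstrap 95% CI; p from the t
approximation. The left/right correlation difference resamples subjects
once jointly per draw and reports the percentile CI of Δrho and
two-tailed p = 2·min(P(Δ≤0), P(Δ≥0)). Bootstrap draws in which a
resampled variable is constant have undefined rho and are dropped (counted
in the result); with n = 16 this is vanishingly rare.

## Synthetic cohorts

Real recordings are not bundled, so every claim is validated on synthetic
cohorts with known injected structure:

- **Background noise**: per-channel 1/f^β spectrum-shaped Gaussian noise
  (β = 1 default, 10 µV expected RMS, analytic Parseval scaling), then
  mixed across channels with an angular-Gaussian kernel (σ = 0.5 rad,
  rows unit-norm so per-channel RMS is preserved). The mixing emulates
  volume conduction: real scalp noise is spatially smooth, and a surface
  Laplacian would otherwise amplify spatially white noise unrealistically.
- **Alpha oscillation**: an ongoing sinusoid (10 Hz default) with a random
  phase per trial, projected through a broad angular-Gaussian gain bump
  (σ = 0.45 rad) centred on the left posterior ROI. On trained trials its
  amplitude is multiplied by (1 + per-subject effect) inside −480…−250 ms
  pre-target, with 50 ms cosine ramps to avoid spectral splatter. Random
  phase makes the effect induced (no ERP counterpart); the broad bump is
  both realistic and what keeps the focal-P1 / broad-alpha distinction
  visible through the spatially high-pass Laplacian.
- **P1**: a target-locked Gaussian bump (latency 115 ms, SD 15 ms, 4 µV)
  projected as narrower bumps (σ = 0.3 rad) over both posterior ROIs; on
  trained trials an additive per-subject increment enters through the left
  bump only (left-lateralized effects are what the analysis is built to
  resolve).
- **Across-subject structure**: per-subject (alpha, P1) effects are drawn
  from a bivariate normal with means at the configured effects, SDs
  defaulting to half the means, and correlation `effect_corr`.
- **Artifacts**: with probability `artifact_rate` per epoch, a 200 ms
  ±100 µV square pulse on a random channel — built to trip the ±75 µV
  rejector. Artifact, noise, alpha-phase and trial-order draws use
  separate per-(seed, subject) streams, so toggling artifacts does not
  change the noise realization, and a subject generated alone is identical
  to the same subject inside a cohort.

What the generator does **not** emulate: ocular/EMG artifacts (the ICA
stage of a real pipeline is a documented no-op extension point),
behavioural responses, realistic head-model forward projection, non-
stationary noise, and cue-evoked responses (off by default; the cue-locked
P1 can be analyzed by re-running the ERP operations with the cue as
reference event). Passing tests therefore establish the correctness and
calibration of the *analysis machinery* under plausible signal structure,
not performance on real recordings.

## Validation studies and problem sizes

`alphap1.validation` packages the simulation studies asserted by the test
suite and reported by `scripts/acceptance.py`. Full-scale cohort defaults
(16 subjects, 180 trials/condition, −1500…+2517 ms epochs, 60 channels)
match the experimental design but are unnecessary for property checks, so
the studies run at a documented desk scale — shortened epochs (−700 ms
pre-cue to +300 ms post-target, which still keeps the pre-cue baseline and
the −500…0 ms pre-target window clear of wavelet edges):

- *Type-I calibration*: 300 null cohorts (16 subjects, 10 trials/cond,
  20-channel posterior-patch montage — with nothing injected there is no
  lateralized signal for a coarse montage to spread), left-hemisphere
  cluster test at 1000 permutations; the significant-cluster rate should
  sit in the binomial 95% band around 0.05.
- *Effect recovery*: 50 cohorts at generator defaults (alpha effect +40%
  amplitude in −480…−250 ms, left-lateralized; full 60-channel montage,
  20 trials/cond); a significant left cluster must overlap the injected
  window in ≥90% of runs while right-hemisphere detections stay at the
  false-positive floor. The full montage matters here: with few channels
  the spline Laplacian spreads the left-posterior topography into the
  right ROI.
- *Permutation oracle*: at n = 8, Monte-Carlo cluster p's vs the exact
  256-pattern enumeration.
- *Wavelet and Laplacian analytics*: pure-tone interior-power constancy
  (< 2% CV), FFT-vs-direct convolution equivalence, constant-field
  annihilation, spherical-harmonic eigenproperty on a 128-channel
  Fibonacci montage.
- *P1 machinery*: noise-free recovery at 115 ms to one sample; monotone
  ramps are undetected.
- *Correlation recovery and coverage*: cohorts with `effect_corr = 0.6`
  at a calibrated effect size (see below); the left-hemisphere Spearman
  estimate must be positive in ≥90% of 100 runs, and percentile-bootstrap
  CI coverage of a true Spearman 0.6 at n = 16 must be within 5 points of
  nominal over 300 replicates.
- *ANOVA identity*: F = t² to 1e-8 over 100 random designs.

**Calibration.** Single-subject effect magnitudes are not identifiable
from published group statistics, so desk-scale effect sizes were
calibrated once, on pilot cohorts, to give the recovery studies ≈90%+
power, and then frozen. The correlation study is the binding constraint:
the Spearman estimate is attenuated by trial-limited measurement noise in
both modulation estimates, so that study uses more trials per condition
and a larger, more dispersed P1 effect than the generator defaults; the
exact values are in `alphap1.validation._corr_config` with the reasoning
in its docstring.

## Numerical choices and edge cases

- Time axes are uniform ms grids anchored at cue onset; the 1017 ms
  cue→target delay places target-relative times on the between-sample grid,
  and all windows select samples by closed-interval comparison with a 1e-9
  ms guard.
- Quantiles of null cluster-size distributions use linear interpolation,
  which softens the discreteness of integer run lengths.
- The spline systems are solved as augmented (constrained) linear systems,
  not explicit inverses; coincident electrodes raise a singular-geometry
  error.
- Degenerate inputs are first-class: all-flat ERP search windows warn and
  return the midpoint; constant correlation inputs raise; zero baseline
  power raises naming the channel/frequency; an all-rejected subject
  raises naming the subject.
- Seeds: every stochastic operation takes an explicit seed; cohort
  generation derives per-subject, per-purpose streams from
  (seed, subject, purpose) tuples.

## Known limitations

- CSD magnitudes are unit-sphere-relative; only contrasts are
  interpretable, which matches every statistic computed here.
- The cluster test controls multiplicity over time within one band and
  ROI, matching an a-priori band/ROI analysis; it does not control across
  frequencies or channel space.
- The single-trial P1 vs behaviour mixed-effects models of a full study
  are out of scope; the single-trial peak table exports cleanly for any
  regression package.
- With very few channels the spherical-spline Laplacian is a coarse
  spatial filter; lateralization claims should use full-head coverage (the
  validation studies do exactly that where it matters).
- Spline-CSD estimates of a lateralized source are not perfectly local:
  on the 60-channel montage the Laplacian of the left-posterior alpha bump
  retains ≈23% of its amplitude (≈5% of its power) at the right ROI —
  far-field ringing of the low-degree spherical-harmonic fit. A
  multiplicative left-hemisphere power modulation therefore appears,
  strongly attenuated, in the right ROI as well, and becomes statistically
  detectable once trial counts push the noise floor below it (observed at
  ≥60 trials/condition in the synthetic cohorts). At the 20-trial recovery
  conditions the right-hemisphere detection rate stays at the
  false-positive floor. Real analyses that interpret "left but not right"
  significance patterns inherit the same caveat.
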