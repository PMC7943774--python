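# Methods

`vnspupil` analyzes parametric vagus nerve stimulation (VNS) experiments in
head-fixed mice: 10-s trains of biphasic pulses, each defined by pulse
amplitude A (mA), width W (ms) and rate R (Hz), delivered every 106–130 s
(uniform, mean 118 s) while pupil area, exposed-eye (eyelid) area, eye
position, treadmill velocity and, in imaging sessions, cholinergic axonal
GCaMP fluorescence are recorded. This note documents the models, the
numerical choices, and what the synthetic data generator does and does not
emulate.

## Signal conditioning

Pupil and eyelid series are resampled to 50 Hz (linear interpolation),
blink-cleaned, low-pass filtered and normalized to percent of the series'
99.9th percentile. Blinks are detected as outliers (default |z| > 3,
configurable) of the z-scored first difference of the pupil series, plus
any frames already flagged missing; each bad span is extended by 150 ms on
both sides and filled by linear interpolation between the nearest good
neighbours (constant extension at the edges). Filtering is a third-order
Butterworth with 3 Hz cutoff applied forward and backward
(`sosfiltfilt`), so evoked latencies are not phase-shifted; the effective
amplitude response is the squared one-pass magnitude, which places the
two-pass −3 dB point slightly below 3 Hz. Interpolation strictly precedes
filtering — filtering an uninterpolated blink smears it across the evoked
band (a regression test checks the spectra). Eye position is z-scored
after interpolating the spans detected on the pupil (both derive from the
same ellipse fit); velocity is only resampled; the calcium trace is
low-passed, detrended by a single least-squares line over the whole
session (photobleaching rundown) and percentile-normalized. Resampling
uses plain linear interpolation rather than a polyphase decimator: every
downstream measure lives below 3 Hz and the subsequent low-pass bounds
aliasing from the 143→50 Hz step.

## Evoked-response scalars

The evoked scalar of a trial is mean(signal in the response window) −
mean(signal in the pre-onset baseline window), windows half-open in
seconds from train onset. Standard-luminance sessions use 2.5–7.5 s
against a 5-s baseline; the dim imaging setup yields much longer pupil
dilations, measured 10–30 s against a 20-s baseline. Calcium responses use
2.5–7.5 s / 5 s in all sessions. Walking is summarized by the mean
velocity over the 10-s train; a trial counts as a walk trial when |mean
speed| strictly exceeds 0.05 cm/s (a speed of exactly 0.05 does not
count). Trials are flagged — never deleted — when more than 25% of the
samples in their measurement windows were interpolated (the "could not
reliably record" operationalization; the source reports only outcome
rates, not the rule), when the epoch is truncated by the session edge, or
when imaging motion exceeds 2 μm in x or y.

## Reversion-to-the-mean correction

Pupil size is strongly autocorrelated and drifts back toward its mean,
which anticorrelates baseline and "response" even without stimulation. For
each train with ≥30 s of clean pre-onset data a pseudo-trial is placed so
that its response window ends exactly at the true onset (pseudo-onset =
onset − response-window end; one pseudo-trial per trial). A cubic of
pseudo-response on pseudo-baseline is fitted to trial-level pseudo data
pooled per experiment kind; eight equal-count baseline bins are reported
as diagnostics only (fitting to bin means discards within-bin
information). The correction subtracts the cubic's prediction at each
real trial's baseline from its response, keeps the uncorrected column
alongside, and refuses to be applied twice to the same column. On
null-effect synthetic sessions the corrected responses show no residual
baseline slope while the uncorrected ones are reliably negative — the
core validity check.

## Dose-response surfaces

Responses are modelled as a separable product of log-logistic growth
terms, either over (A, W, R) (seven parameters: s, a1, b1, a2, b2, a3,
b3) or, reduced, over charge per pulse C = A·W and R (five parameters).
Each a_i is its factor's half-maximal value; the reduced-model a1 is the
charge at half-maximal response. Fits are trial-level unweighted nonlinear
least squares (`scipy.optimize.least_squares`, TRF with bounds),
multi-started from the {25, 50, 75}th percentile of each factor (taken
jointly) crossed with shape starts b ∈ {1, 2}; bounds a_i ∈ [min/10,
max·10], b_i ∈ [0.1, 20]. The scale s is positive for pupil/calcium, free
signed for eyelid/walk, and in magnitude bounded by 5× the largest
absolute cell-mean response: when the tested range ends below the plateau
(double-cut condition), s and a1 are only jointly identified through
s/a1^b and an unbounded s lets fits escape along that power-law ridge.
A point worth knowing: a separable product of log-logistics in A and W
cannot exactly represent a log-logistic in A·W (only power laws factor
through a product), so on exactly charge-equivalent data the full model
retains a small structural deficit (~3% of signal variance at the default
truth) rather than matching the reduced model to arbitrary precision.

Charge bins are five equal log10-width intervals over the tested charge
range (0.01–0.72 μC for the standard grid), labelled no-effect / optimal
×3 / off-target. Bin-wise tests are two-sided one-sample t tests against
zero (pupil, eyelid, walking) or paired t tests of each upper bin against
the lowest bin (calcium, whose region of interest was defined by its own
responsiveness — testing it against zero would be circular), corrected by
Benjamini–Hochberg FDR at q = 0.05 (statsmodels). The half-max charge's
uncertainty is the SD of a1 over trial-resampled refits (default 5000),
warm-started at the full-sample solution; two conditions are compared by
p = 2·min(Pr(Δ≤0), Pr(Δ≥0)) over paired draws, floored at 2/n_boot.

## Engagement and mediation

Nerve engagement N is the out-of-fold surface prediction of the pupil
response: trials are partitioned into 20 seeded folds stratified by charge
bin (so every training set spans the dose range), the full surface is
fitted on 95% and evaluated at the held-out 5%. The mediation system is
three OLS fits on aligned non-artifact trials with walking excluded by
default: P = i0 + cN, C = i1 + aN, P = i2 + c′N + bC, giving indirect
effect a·b and proportion mediated a·b/c (reported only when |c| > 2
SE(c)). The OLS identity c = c′ + a·b is asserted to 1e-8 on every fit.
Inference is a trial-resampled bootstrap (default 5000) reporting draw
distributions and the fraction of draws below zero. Note that
cross-validated predictions of exchangeable noise are mildly
*anti*-correlated with held-out values (a finite-sample property of CV),
so the honesty check for label shuffling is one-sided.

## Auxiliary statistics

Sequential polynomial regression builds [1, X, X²], orthogonalizes by QR,
and adds one order at a time; each step's F is the drop in residual sum of
squares over the highest-order model's residual mean square, and BIC =
n·ln(SS/n) + k·ln(n) (Gaussian form without additive constants — they
cancel in differences), with a higher order preferred by BIC only at
ΔBIC ≥ 10. The pixelwise cluster test thresholds one-sample t maps at the
two-sided p < 0.05 t quantile (the cluster-forming level is not dictated
by the source and is configurable), clusters suprathreshold pixels by
4-connectivity separately for positive and negative excursions, scores
clusters by summed t, and builds the null of the maximum cluster score
from seeded per-trial sign flips; cluster p = (1 + #null ≥ obs)/(1 +
n_perm), significance at p < 0.01. Sign flips preserve E[x²] per pixel,
which the implementation exploits to avoid touching the data matrix per
permutation. Phase-locked eye-movement power uses a 1-s Hann spectrogram
(0.25-s hop), expresses power as percent change from the −5.5 to −0.5 s
baseline, and takes the mean change during the train at the frequency bin
nearest the train rate.

## Stimulation electronics

The leak fraction is L = 1 − Am/Ai with Am the mean across the minimum
measured amplitude per (width, rate) group, restricted to widths ≥ 0.4 ms
— the 0.1/0.2 ms pulses are attenuated by the output filter and would
masquerade as leak (this exclusion leaves a ~0.2% residual bias from the
0.4 ms pulses, inherent to the rule). The width filter is a least-squares
sigmoid Am(W) = s/(1 + exp(−a(W − b))) over the tested widths; flat
profiles are detected and reported as degenerate rather than fitted.

## Synthetic sessions

The generator produces exactly the statistical structure the analysis
assumes — no more. Baseline pupil is an exact-discretization
Ornstein–Uhlenbeck process (τ = 40 s, stationary SD 6%, mean 50% of the
normalization scale), chosen because mean reversion is precisely the
confound the correction targets. Evoked transients are peak-normalized
difference-of-exponentials kernels (standard: rise 2.5 s / decay 12 s,
peaking ≈5 s after onset; imaging pupil: 6/25 s; calcium: 1.5/8 s) scaled
by the dose surface at the train's parameters times mean-preserving
log-normal trial noise (σ = 0.4), plus additive noise. The default pupil
truth is reduced-form with half-max charge a1 = 0.15 μC and the additive
scalar noise (SD 3.45%) is calibrated so the trial-level variance
explained of the reduced fit equals the reported 26.33% — the only
quantitative trial-level noise anchor available; eyelid (0.32 μC),
calcium (0.062 μC) and walk probability (0.17 μC, saturating at 45%) use
their reported half-max charges. A configurable proportion (default 0.5)
of the pupil's trial noise is shared with calcium, making calcium a
partial mediator. Walking bouts occur per train with probability from the
walk surface at ≈0.35 cm/s with a 3-s decay, over sparse spontaneous
bouts; blinks are Poisson dropouts (2/min) with occlusion transients at
their edges; grounded sessions add a sinusoid at the train rate to eye
position during trains; measured current is intended × (1 − L) ×
sigmoidal width filter. `generate_image_stack` returns per-trial
evoked-response pixel maps plus the ground-truth mask — the object the
cluster test consumes — rather than a raw fluorescence movie, since
frame-level registration is out of scope.

What the generator does **not** emulate: pupillary light reflexes and
luminance coupling, saccade kinematics, foreshortening artifacts,
session-to-session and animal-to-animal heterogeneity, slow non-OU state
drift (sleep pressure), or any biophysics of the NTS/LC/basal-forebrain
circuit. Passing tests therefore demonstrate statistical correctness of
the pipeline under its own assumptions, not biological validity on real
recordings.

## Problem sizes and determinism

All randomness descends from explicit seeds; two runs with the same
configuration are numerically identical. Simulation studies use sizes
chosen to make Monte-Carlo error small relative to the tolerance being
checked: surface recovery at 45 repetitions × 60 combinations (2700
trials) × 100 seeds at the scalar level (statistically identical to full
time-series simulation followed by perfect epoching); correction validity
on three full 2-h time-series sessions; mediation recovery at 180 trials
× 100 replicates; FDR and cluster calibration at 200 null datasets (1000
permutations, 64×64, 12 trials). An observation from the recovery study:
at noise calibrated to the reported variance explained, the Monte-Carlo
SD of the recovered half-max charge at n = 2700 is ≈0.016 μC — about 11%
of the true 0.15 μC and consistent with the reported bootstrap SD of
0.02 μC — so roughly a quarter of replicates fall outside ±10% of truth;
this is a property of the study conditions, not of the estimator.

## Known limitations

Half-max estimates for conditions whose midpoint lies near the top of the
tested charge range (double-cut) are right-skewed even with the plateau
bound; the bootstrap SD reports this honestly. The paired `vs_lowest_bin`
test pairs by within-cell rank after sorting, an arbitrary but
deterministic convention for unequal cells. The bundle format is a plain
CSV/JSON convention of this package, not an acquisition format.
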