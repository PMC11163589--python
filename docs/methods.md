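# Methods

This note documents the models, the numerical choices, and the synthetic
study conditions the package implements, in the order the analysis chain
runs them.

## Trial design

The adult design fully crosses attention (passive, active) × cue
(intensity, spectral) × motion (looming, receding, static with near onset,
static with far onset), giving 16 cells; the default of 100 trials per cell
yields 1600 trials with the passive part always first (listeners must meet
the active task naive). Half of all trials are static catch trials by
construction, since the two static onset renderings are two of the four
motion levels. Within every cell, presentation sides split exactly in half,
which is why `trials_per_condition` must be even.

The newborn design is passive-only. Its 400 trials / 100 per condition are
interpreted as 4 cells = cue × {moving, static}; inside a moving cell
looming and receding each take half the trials and inside a static cell the
near/far onsets do, with sides balanced per cell. This cell definition is a
documented choice: the alternative (cue × motion with 4 motion levels)
cannot produce 4 cells.

Blocks are homogeneous in cue and side (both are manipulated block-wise)
with a configurable block length (default 50); motion labels are shuffled
within each (cue, side) stratum and chunked, so the moving/static mix is
randomized while stratum-level balance stays exact. The change-time jitter
("600 ± 50 ms") and the active inter-stimulus jitter ("800 ± 50 ms") are
drawn from continuous uniform distributions over the stated bounds — the
distribution itself is unspecified in the source description, and the
uniform is the maximally uninformative choice within the bound. The passive
ISI is fixed at 500 ms. Static trials carry a bookkeeping `change_time` but
render no transition.

## Stimulus synthesis

The carrier is a sum of equal-amplitude cosines at k·F0 for all k·F0 in
[1, 16] kHz (151 partials at F0 = 100 Hz), with generalized Schroeder
phases φₖ = c·π·k(k+1)/K over the K in-band partials, c ∈ [−1, 1]
(default 0.5). The exact phase convention of the original stimulus code is
not recoverable from its description; this rule reproduces the defining
property (magnitude spectrum independent of c, crest factor strongly
dependent on it) and is isolated in one function so an alternative can be
substituted. Audio defaults to 48 kHz (the original rate is unstated);
duration 1.2 s with 10 ms squared-sine edge ramps.

Moving trials crossfade between two renderings with a 10 ms linear ramp
whose fade-in and fade-out weights sum to one at every sample. For the
intensity cue both renderings share the native spectrum and sit at +2.5 dB
(near) and −2.5 dB (far) around the unstepped rendering, so a looming trial
steps +5 dB across the transition. For the spectral cue the far rendering
is the native HRTF-filtered carrier and the near rendering the
flat-spectrum version, both normalized to equal broadband RMS so the
overall level carries no information; "near = flat" matches the mapping in
which flattening internalizes the percept. Static trials hold the onset
rendering throughout.

HRTF filtering is zero-phase magnitude filtering on the real-FFT grid
(linear interpolation of the tabulated dB response, edge-hold outside its
support). Only the magnitude profile defines the spectral cue as
implemented, so no minimum-phase reconstruction is attempted. The flat
reference matches mean linear power over the stimulus band per ear and is
idempotent. Both ears are always rendered (ipsilateral and head-shadowed
contralateral responses); the trial's side decides the channel mapping.

Anthropometric individualization scales the template frequency axis by the
weighted geometric mean of (template/listener) pinna-cavity-height and
head-width ratios (default weights ½, ½; template 44 mm / 134 mm). The
exact combination rule of the original scaling procedure is unspecified;
the geometric mean is symmetric in the two measures, reduces to identity
for the template itself, and sends a listener twice the template's size to
features at half the template frequencies. A synthetic template HRTF (shelf
plus pinna notch, shadowed contralateral ear) ships in code because no
measured set can be redistributed; it is labelled synthetic wherever it
appears.

## Hierarchical LBA

Each trial is a race between a correct-response and an incorrect-response
accumulator for its (cue × motion) condition: start point ~ U[0, A], drift
~ N(vᵢ, s_v), threshold b, plus non-decision time t₀. The drift scale s_v
is fixed to 1 — the conventional identification constraint; it is exposed
as a module constant. Per participant the model has 11 free parameters
(8 drifts + A, b, t₀ shared across conditions). The first-passage density
and defective CDF use the standard closed forms with a degenerate-limit
branch for A → 0. The trial log-likelihood is
log f_winner(rt − t₀) + log(1 − F_loser(rt − t₀)), −∞ for rt ≤ t₀.

All "N(m, s)" prior notations are read as (mean, **standard deviation**) —
stated prominently because the variance reading changes every result.
Participant-level parameters carry positive-truncated normal priors under
group-level locations and scales; location hyperpriors are N⁺(2, 1) for A
and b, N⁺(3, 1)/N⁺(1, 1) for correct/error drifts, N⁺(0.2, 0.1) for t₀;
scale hyperpriors are Gamma(shape 1, scale 1), except scale 3 for t₀. The
support enforces b > A through a −∞ log posterior.

### DE-MCMC sampler

Chains start from the documented start distributions (A ~ N⁺(2, 0.2),
b ~ N⁺(1, 0.1), v_c ~ N⁺(3, 0.3), v_e ~ N⁺(1, 0.1), t₀ ~ N⁺(0.2, 0.02)),
with two safeguards: b is drawn conditioned on b > A (the nominal start
means would otherwise place essentially every start in the invalid region),
and t₀ starts are capped below 0.9 × the participant's fastest response so
the likelihood is finite from iteration one.

Each iteration updates, per chain: every participant's 11-parameter block
with the crossover proposal θ* = θ + γ(θ_m − θ_n) + U(−10⁻³, 10⁻³)
(donors m ≠ n ≠ self, γ = 2.38/√(2·11)), followed by one random-scan
single-parameter DE move per participant (γ = 2.38/√2) — added because the
joint move's acceptance is governed by the well-identified dimensions and
leaves weakly identified ones (notably A) mixing far too slowly — and then
the group level as 11 independent (location, scale) pairs (γ = 2.38/√4,
five sweeps per iteration; these conditionals never touch the likelihood,
so the sweeps are nearly free and sharpen group-level mixing). No migration
or purification steps are used. The full-scale configuration is 32 chains ×
8000 iterations with 6000 burn-in and thinning 5; the recovery analyses in
this repository run 8 chains × 2000 (1000 burn-in), which the diagnostics
show to be converged (max group-level split-free R̂ ≈ 1.06–1.09) at the
simulated data sizes used here.

Convergence is assessed with the classical between/within-chain potential
scale reduction factor; degenerate (zero-variance) chains yield NaN rather
than an error. Posterior predictive checks draw 50 random retained samples
per chain (configurable), simulate datasets matching the observed
per-condition trial counts, and report (a) the proportion of simulated RTs
inside the observed interquartile range (reference 0.5) and (b) the
simulated-minus-observed hit rate (reference 0), each with a 95% credible
interval and a two-sided Monte-Carlo p-value.

### Ratio statistic

For each of 10,000 repetitions one joint posterior draw supplies the
group-level (μ, σ) of the looming-correct and receding-correct drifts; N =
10,000 Gaussian drifts per direction are generated and r is the fraction of
pairs with v_L − v_R > 0. Drawing (μ, σ) jointly from the same posterior
iteration (rather than independently across iterations) preserves their
posterior correlation; this reading of "sampling the mean and variance" is
a documented choice. Only correct-response drifts enter — the bias is about
evidence for correctly discriminated motion — also a flagged choice, since
the bare formula does not restrict the accumulators. Pooling across cues
concatenates both cues' drift samples from the same draw before pairing.
The long-run mean of r for fixed hypers equals Φ((μ_L−μ_R)/√(σ_L²+σ_R²)),
which the tests use as an independent oracle. The credible interval is
one-tailed at 89% (lower bound = 11th percentile of the r distribution).

### Simulation conventions

Races in which every drift is non-positive never finish; the simulator
redraws such trials, i.e. it conditions on a response occurring. The
unnormalized defective density is used in the likelihood, standard LBA
practice; at the parameter ranges involved here the non-finish probability
is ≤ 10⁻³, so the discrepancy is far below sampling noise.

## ERP analysis

Filters are windowed-sinc linear-phase FIRs applied with group-delay
compensation and reflect-padding; the printed "n" of each filter is read as
the filter *order* (taps = n + 1), the only reading under which every
quoted high-pass has the odd tap count a type-I high-pass design requires.
Adult recipe: 0.5–100 Hz Kaiser (β = 7.2, order 462) → onset epochs
[−200, 1500] ms → −200/800 µV hard threshold → average reference →
change epochs [−550, 850] ms → trial-count equalization → 20 Hz Hamming
smoothing (order 150) → 100 ms pre-event baseline; a pipeline recorder
asserts this execution order in the tests. Newborn recipe: 0.05 Hz
high-pass (Hamming, order 33000) and 80 Hz low-pass (order 84) at 500 Hz
(the printed "500 kHz" sampling rate is treated as 500 Hz, consistent with
the 100 Hz online anti-aliasing filter), average reference, change epochs
[−100, 800] ms with baseline, ±100 µV threshold, equalization, 20 Hz
smoothing (order 140).

Epoch windows are closed intervals on the sample grid (so [−550, 850] ms at
1 kHz holds 1401 samples). Equalizing x = y − m removals from a y-trial
condition removes the trials at 1-based positions round-half-up(k·y/x),
k = 1..x — spreading removals evenly (y = 10, x = 2 removes the 5th and
10th) while preserving survivor order. Participants keeping fewer than 60%
of designed trials in any condition are excluded; the boundary is
inclusive. Bad-channel handling (interpolation, ICA, visual inspection) is
represented only as an externally supplied rejection-mask interface and is
never computed here.

N1 is the largest-magnitude *strict local* negative extremum within
82–182 ms post-change (77–177 ms for source-style traces); window endpoints
never qualify. P2 is the largest strict local positive extremum within
150 ms after the found N1. Traces without a qualifying extremum return
found = False, and such participants are dropped listwise from the affected
component's statistics. Biases are differences of per-condition peaks (not
peaks of difference waves) — the reading consistent with extracting peaks
"for all considered conditions"; flagged as a choice.

The 2×2 within-participant ANOVA uses the standard
participant-by-condition sums-of-squares decomposition (each effect's F
equals the squared paired t of its contrast — the property the brute-force
test oracle checks), generalized eta squared by the additive-SS definition,
and report-only sphericity/normality notes (2-level factors make Mauchly's
test trivial; df are (1, N−1) throughout). Follow-up contrasts are paired
t-tests with paired Cohen's d (mean difference / SD of differences) and a
seeded BCa bootstrap CI (10,000 resamples by default) — the original
effect-size routine is a black box, so the CI method is a documented local
choice.

## Cluster-based permutation tests

The paired-t map over (channel, time) is thresholded at the two-tailed
α = 0.05 t-quantile (df = N − 1); suprathreshold samples of each sign are
grouped by connectivity over adjacent channels and consecutive samples, and
summed t values form the cluster statistic. The reference distribution is
the per-permutation maximum of |clusterstat| under independent
per-participant sign flips, so both signs are tested jointly — one of
several two-tailed conventions in common practice, chosen for symmetry.
Monte-Carlo p-values carry the +1 correction, p = (1 + #{maxima ≥
|observed|})/(1 + n_permutations), guaranteeing p > 0; when 2^N ≤
n_permutations the full flip set is enumerated and p is exact. Channel
adjacency defaults to a distance threshold of 1.3 × the median
nearest-neighbor distance (no neighborhood definition is given in the
source description); k-nearest with union symmetrization is available.
Cohen's d per significant cluster is computed on participant-wise
differences averaged over the full cluster mask, with the peak sample
reported separately. A temporal-only mode treats a channel-cluster average
or region time series as one virtual channel.

Validity is established empirically in the tests: exact agreement with the
2⁶ enumeration at N = 6 within Monte-Carlo tolerance, and an empirical
type-I error of ≈ 0.05 over 200 null simulations at reduced size
(8 participants, 4 channels × 30 samples, 200 permutations).

## Synthetic data: what it does and does not emulate

Behavioral ground truth: shared-parameter group locations follow the
reported adult group-level values (A = 0.573, b = 1.694, t₀ = 0.139 s);
drift locations sit at the prior centers (3 correct / 1 error, giving
realistic ~80–90% discrimination accuracy); between-participant scales are
moderate (0.35/0.35/0.08 for the shared parameters, 0.3 for drifts) so a
dozen simulated participants remain informative. Looming and receding
drift locations are *equal* by default — the generator encodes the null,
so ratio-statistic behavior under no bias is testable; biased datasets are
one parameter change away.

EEG epochs are: a shared N1/P2 template (windowed Gaussians, N1 −3 µV at
120 ms width 30 ms, P2 +2.5 µV at 220 ms width 50 ms — placed inside the
peak-search windows so extraction tests are meaningful), plus a half-sine
looming-minus-receding bias (default 1.5 µV over 100–250 ms on a
frontocentral channel group), plus noise that is spatially correlated
(exponential distance kernel — the simplest structure that makes
adjacency-based clustering nontrivial) and 1/f-shaped in time, with
multiplicative per-participant amplitude jitter. The synthetic cap is a
ring plus vertex. Not emulated: forward-modeled source topographies,
ocular/muscle artifacts, non-stationary sleep EEG, bad channels, and
latency jitter of the components across trials. Passing tests therefore
demonstrate the *statistical machinery* (detection, calibration, recovery)
under known truth, not performance on real recordings; data-dependent
quantities of the original study (fitted parameter values, cluster
latencies, effect sizes) are not reproduction targets.

## Problem sizes used in the shipped analyses

Recovery and analysis runs use 12 participants × 50 trials/condition with
8 chains × 2000 iterations; the credible-interval coverage study runs 20
repetitions of 4 participants × 30 trials with 6 chains × 500 iterations;
cluster-test calibration uses 200 null datasets of 8 × 4 × 30 at 200
permutations. These sizes were chosen so a complete desk run finishes in
minutes on a single CPU while keeping every statistical check adequately
powered; the full-scale study settings remain the defaults of the
"study" profile in `loombias.pipeline`.

## Known limitations

- The sampler is a practical blocked DE-MCMC, not a gold-standard gradient
  sampler; very weakly identified parameters (A at small trial counts)
  carry wide, prior-influenced posteriors — visible in the recovery runs as
  large posterior SDs rather than biased point estimates.
- HRTF processing is magnitude-only; interaural time cues are not
  rendered.
- The ERP pipeline operates on synthetic or imported continuous data;
  artifact handling beyond hard thresholds is out of scope by design.
- The exact phase rule, frequency-scaling formula, and cluster two-tailed
  convention of the original tools are replaced by the documented defaults
  above; each is isolated behind one function for substitution.
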