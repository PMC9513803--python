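# Methods

`wnspike` analyzes spike trains of neurons driven by repeated presentations
of a fixed, filtered Gaussian white-noise (WN) stimulus, and infers how
faithfully and at what timescale the stimulus is represented — single-unit
decoding quality, spike-timing precision, reliability timescale — plus
monosynaptic connectivity between simultaneously recorded units and
data-driven models of convergent spike transmission. This note documents the
models, the estimators, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Stimulus model

The stimulus is zero-mean Gaussian white noise sampled at `fs` (default
6 kHz), convolved with an alpha function `t·exp(−t/τ)` (τ = 3 ms, support
truncated at 10τ, which captures >99.95% of the kernel mass; unit-sum
normalization, irrelevant after scaling), then min-max scaled to [0, 1].
One fixed 1 s realization is reused across all trials. The light-power
command is the affine map `P(t) = μ + x(t)·σ`, with μ required to keep all
samples positive. Analyses standardize the trace to z(t) (zero mean, unit
variance) and resample it to the 2.5 kHz analysis grid (polyphase,
zero-phase). Convolution edges are zero-padded; the kernel degenerates to a
one-sample identity when 10τ falls below the sample spacing.

## Point-process simulator

A simulated unit is the superposition of a *signal* and a *noise* train:

* The signal rate profile f(t) is the standardized stimulus convolved
  (causally) with one cycle of a 100 Hz sinusoid — a simplified
  spike-triggered-average-like template — rectified at zero and scaled so
  its time average equals λ₁. Causal alignment matters: it puts the
  driving stimulus feature *before* the spike, which fixes the sign of the
  decoded time lag.
* A "mother" train is drawn per unit by per-sample Bernoulli sampling with
  probability f(t)/fs, then thinned causally to a minimum inter-spike
  interval (default 2 ms, within the 1–5 ms range typical of absolute
  refractoriness).
* The mother is replicated into N = 25 per-trial "daughters"; each daughter
  is degraded by (1) Gaussian spike-time jitter of SD σ₁, clipped to the
  trial, (2) removal of `k ~ Uniform{0..N_remove}` spikes, (3) addition of
  `k ~ Uniform{0..N_add}` spikes at uniform times ("up to N" is read as a
  uniform draw; recorded in metadata). The noise train repeats this with
  rate λ₂ and jitter σ₂; the same N_add applies to both trains. Signal and
  noise daughters are merged per trial.

Jitter can move daughter spikes closer than the refractory interval; the
minimum ISI is enforced only at mother generation, deliberately. All
randomness derives from per-(unit, role) PCG64 streams spawned from one
master seed, so extending an experiment never perturbs existing units.

What the generator does **not** emulate: slow excitability drift across
trials, bursting, adaptation, trial-varying latency, and cross-unit noise
correlations. Consequently trials share the mother's structure at *every*
timescale, which makes synthetic units more decodable than recorded ones at
matched rates (see "Overfitting by shared structure" below).

## Reconstruction and decoding quality

A filter model maps spikes back to the stimulus: reconstruction
ẑ(t) = Σ_j c(t − T_j), with c one of six base filters over lags ±50 ms
(251 taps at 2.5 kHz), each in causal (positive lags zeroed) and acausal
form — the twelve cross-validated models:

* **STA** — mean standardized-stimulus segment around each spike
  (zero-padded at trial edges; exclusion selectable).
* **Conditional STA** — spikes tagged by the decile of their preceding ISI
  (ten equally populated bins; a trial's first spike takes the ISI across
  the inter-trial gap when available, else the top decile); one STA per
  decile. Tied decile edges raise an error.
* **Wiener** — STA computed on the whitened stimulus. Whitening builds the
  biased Toeplitz autocovariance over the filter window, eigendecomposes
  it, keeps the leading eigenvalues covering ≥90% of variance, and applies
  the symmetric pseudo-inverse square root as an FIR filter (its center
  row). The retention threshold prevents amplification of the stimulus's
  empty high-frequency band.
* **Modified Wiener** (the headline model) — the STA deconvolved by the
  spike-train autocorrelation: solve `A w = s` where A is the symmetric
  Toeplitz matrix of the per-spike-normalized autocorrelation histogram
  (ACH) on the analysis grid. The ACH is measured out to twice the filter
  window (the operator needs lags to 2×50 ms); its zero-lag bin carries
  each spike's self-coincidence (value 1 per spike), which makes A
  identity-like for a Poisson train and well conditioned in general. The
  solve uses Levinson recursion with a residual check, falling back to an
  eigendecomposition with eigenvalues floored at 1e-6 of the maximum.
* **PWSTA** — the Wiener filter gauged against the whitened stimulus
  (both sides whitened).

Decoding uses 10-fold cross-validation over trials (contiguous folds): the
filter is fit on 90% of trials and each held-out trial is reconstructed
and scored by the Spearman rank correlation q_i = ρ(z, ẑ_i) (average-rank
ties). Q is the mean over trials; zero-spike trials are excluded and
counted. Per-trial significance comes from reconstructing `n_shuffles`
uniform redraws of that trial's spike times with the same filter:
p_i = (1 + #{q_shuffled ≥ q_i})/(n_shuffles + 1), and the overall p is the
geometric mean of the p_i. The add-one rule keeps every p strictly
positive, which the geometric mean requires; note the per-trial floor
1/(n_shuffles+1) also floors the geometric mean, so borderline units need
enough shuffles (default 100) for a resolvable overall p. The reported
time lag is the negative of the filter's peak lag (positive = stimulus
precedes spike).

### Overfitting by shared structure

Any spiking structure that repeats across trials — not just the
stimulus-locked component — inflates Q, because the training-set filter
partially memorizes the stimulus segments around repeated spike times and
the test trials repeat those times. Cross-validation over trials cannot
remove this; for a 251-tap filter the effect scales roughly with the ratio
of filter taps to trial samples. The within-trial shuffle test remains
valid (shuffling destroys the repeated structure), but absolute Q values
of highly reliable synthetic units should not be compared with recorded
ones. The null-calibration test therefore uses trains with trial-independent
spikes.

## Precision (interval jitter)

Precision P is the smallest jitter half-window δ whose application
consistently degrades Q. Interval jitter partitions the trial into fixed
windows of width 2δ anchored at zero and redraws each spike uniformly
within its window — spike count and coarse rate structure are preserved
exactly. The sweep runs δ = 0.4·2^k ms, k = 0..8 (0.4–102.4 ms): test-set
spikes are jittered (default 10 realizations, averaged within trial;
training filters are reused, not refit) and the per-trial q are compared
with the unjittered q by a one-tailed Wilcoxon *rank-sum* (Mann-Whitney)
test. The rank-sum form is essential: a paired signed-rank test detects
the sign-consistent but negligible Q drop that any jitter produces in
nearly every trial and would return P ≈ the smallest tested δ for every
unit, regardless of its true timing jitter; the rank-sum test requires
degradation to exceed the trial-to-trial spread of q, and recovers
injected jitter near unity. A focused sweep of 10 log-spaced δ inside
[largest coarse δ without deterioration, smallest with] (one octave below
when deterioration is already present at 0.4 ms) refines P; the smallest
focused δ with p < 0.05 is reported, the coarse detection otherwise. If no
δ up to 102.4 ms deteriorates Q, P is flagged undetected (+inf sentinel).

Precision is defined only for units with a consistent stimulus-locked (AC)
response (decoding p < 0.05). The parameter-recovery studies bypass this
gate (`require_screen=False`): at large injected jitter the gate rejects
virtually every unit, which would make the recovery claim untestable
rather than falsifiable; the gate is a data-quality filter for recorded
units and stays in force everywhere else.

Because P is a detection threshold, it depends on statistical power: units
with more spikes or more trials resolve smaller degradations. Comparisons
of P across populations should therefore be made at matched rates, as
the transmission study below does.

## Reliability timescale and coder classes

Trials are "reconstructed" by summing unit-mass Gaussians (SD σ) at the
spike times, evaluated exactly at the continuous spike times over ±8σ.
The estimate is divided by the kernel mass inside the trial window
(boundary/coverage correction). This correction is load-bearing: without
it every trial shares a deterministic dome-shaped envelope at large σ
(mass lost at the edges), which pins trial-pair correlations near 0.5–0.8
at the top σ for any spiking whatsoever and forces monotone profiles.

Reliability r(σ) is the mean Spearman correlation over all N(N−1)/2 trial
pairs of the smoothed traces, on the same log-spaced grid as the jitter
sweep (0.4–102.4 ms). If the coarse peak is interior, 10 log-spaced σ
between its two coarse neighbors refine the profile (symmetric extension
of the refinement interval). Rp is the σ of the global maximum; ties go to
the smallest σ. Consistency is a one-tailed Wilcoxon test that the pair
correlations at Rp exceed zero.

Classification: *temporal* if the coarse profile has an interior local
maximum whose trial-pair correlations consistently exceed both flanking
local minima (one-tailed Wilcoxon, p < 0.05 each side), or an interior
global maximum exceeding the top-σ value by more than twice the summed
standard errors (an effect-size guard — with hundreds of pairs a paired
test would resolve arbitrarily small dips); a temporal coder may still
have a second maximum at the top σ. *Rate* if the top-σ value reaches the
global maximum within that tolerance and no decrease along the profile
exceeds two standard errors. Everything else is *undefined*. The per-unit
consistency rule is this package's own operationalization; a group-level
nonparametric test on pooled profiles is the more robust alternative for
population claims.

A structural fact governs all of this: when every trial has the same
spike count and no unshared spikes, the profile increases monotonically
and Rp sits at the top σ. Interior peaks require unshared (added or
removed) spikes. More fundamentally, in the mother/daughter generator the
expected profile is non-decreasing in σ — enlarging the kernel only
improves the overlap of the shared jittered spikes, while the unshared
variance scales the same way — so for noise jitter beyond roughly a tenth
of the largest tested σ the argmax saturates at the grid ceiling. The
recovery study (25 trials, λ₁ = 100, σ₁ = 10 ms, λ₂ = 200, N_add = 25,
the degradation level of the printed example configurations) therefore
reports, alongside the argmax medians, the profile's *half-rise
timescale* (smallest coarse σ reaching half the profile maximum), which
tracks the noise jitter across its whole range.

## Monosynaptic connectivity

For a directed pair, the count cross-correlogram (CCH; 0.4 ms bins,
centered half-open bins spanning ±50 ms, odd bin count) is built from
spike times in stimulus-free epochs. The baseline is a centered 25-bin
(10 ms) median filter of the count CCH with reflected edges (window
configurable). Detection: per bin of the monosynaptic region of interest —
13 whole bins covering (0, 5.2] ms — the upper-tail Poisson probability of
the observed count given the baseline expectation, Bonferroni-corrected by
13; significant at α = 0.001. The plug-in baseline is noisy at low counts
and inflates the type-I rate when bins expect only a few coincidences;
with session-realistic sizes (≈15 expected counts per bin) the detector
holds its nominal level.

The spike transmission curve deconvolves both the count CCH and its
baseline by the presynaptic ACH (same per-spike normalization and
regularized Toeplitz solve as the modified Wiener filter; the ACH spans
±100 ms so the operator covers all lag differences), subtracts, and scales
by presynaptic spike count and bin width to spikes/s. The gain is the
trapezoidal integral of the excess rate over the peak's support — the ROI
peak extended to its zero crossings — and estimates the expected number of
excess postsynaptic spikes per presynaptic spike; injected transmission
probabilities are recovered within ~12%. Connection probability divides a
unit's presynaptic partners by the simultaneously recorded pyramidal cells
within 600 μm (Euclidean over shank spacing × shank index and depth).

## Transmission models (synthetic interneurons)

Each presynaptic train is convolved per trial with the pair's transmission
curve (strictly positive lags, negative excess clipped) to give a rate
x_i(t). Combination rules, with n(t) = #{i : x_i(t) > 0} and products/sums
over active inputs only (making the n = 1 and n = 0 cases the continuous
limits):

* LL (labeled line): y = x, single input.
* SP (summed population): y = Σ x_i.
* CD1 (synaptic multiplication): y = Π(x_i + γ) − γⁿ for n > 1.
* CD2 (nonlinear summation): y = (Σ x_i)·γ^(n−1) for n ≥ 1.

γ ≥ 0 sets the coincidence amplification; it carries rate units in CD1 and
is dimensionless in CD2. CD2 with γ = 1 is exactly SP; any rule with one
input is exactly LL. "Simultaneously active" means x_i(t) > 0 at the
sample (threshold configurable). ST₁ is sampled from y by the simulator's
Bernoulli scheme (no minimum ISI by default); its realized rate FR₁ is
measured, and if FR₁ < FR_WN (the target's observed stimulation rate),
homogeneous Poisson background at FR₂ = FR_WN − FR₁ is merged in; the
noiseless variant skips the background.

The error-correction study drives a CD2 target from eight simulated
pyramidal cells at their observed operating point (≈12 spikes/s of which a
third is incoherent background, 3 ms signal jitter, decoding quality
≈ 0.13), with pair gains uniform in 0.01–0.03, FR_WN = 28 spikes/s, and
γ = 2× the median single-synapse peak drive (the regime where pairwise
coincidences dominate the output). Error correction arises from two
cooperating effects — coincidence selection of signal-locked spikes and
the higher postsynaptic rate — while the precision gain is weaker and
rests mostly on noise rejection; matched LL and SP targets deliver almost
all their rate as equalization background and fail the AC screen.

## Screening and shared statistics

Unit inclusion is a sequential funnel: ≥5 trials and ≥2 spikes/trial with
a DC response (stimulation rate / spontaneous rate consistently above 1;
upper-tail Poisson test on the pooled count), then an AC response
(decoding p < 0.05), then consistent reliability (pair correlations above
zero). α = 0.05 throughout, except monosynaptic detection at α = 0.001.
The spontaneous rate comes from explicitly labeled stimulus-free epochs.

Shared tests: Spearman correlation with a two-sided permutation p
(add-one counting; partial variant via rank residuals against a
covariate), one-tailed Mann-Whitney U and paired Wilcoxon signed-rank
tests, the G test of independence (log-likelihood-ratio χ²), exact
one-tailed binomial, and the upper-tail Poisson test. The Poisson test is
exact and hence conservative at small expectations; its type-I calibration
is run at expectation 400 (e.g., an 8 spikes/s baseline over 50 s), where
the discrete attainable level sits inside the nominal band.

## Validation studies and problem sizes

The studies behind `scripts/acceptance.py` and `tests/test_acceptance.py`
use: 20 seeds per condition; 25 trials of 1 s per unit; 40 within-trial
shuffles for screening (200 for the borderline synthetic-interneuron
targets, where the geometric-mean floor matters); 5 jitter realizations
per δ; 2000 simulations for test calibration with 99 permutations each;
1000 null pairs at session-realistic sizes for the detector calibration.
These sizes are the studies' design choices; all thresholds are stated in
the tests themselves.

## Known limitations

* Absolute Q of highly reliable synthetic units is inflated by the shared
  mother structure (see above); orderings and recoveries are unaffected.
* P and Rp are detection-based and therefore power-dependent; compare
  across conditions only at matched rates and trial counts.
* The classifier's per-unit consistency rules are the package's choice of
  operationalization; group-level inference should use the stated
  nonparametric tests on the profiles directly.
* The connectivity detector assumes a known baseline; at very low
  coincidence counts it becomes anti-conservative and pairs should be
  pooled over longer stimulus-free epochs.
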