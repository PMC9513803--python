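# wnspike

Spike-train analysis of neurons driven by repeated filtered white-noise
(WN) stimulation — as in optogenetic experiments where the same 1 s
alpha-filtered Gaussian noise waveform is presented many times to a small
group of cortical neurons. The package quantifies, per unit, how well and
at what timescale the stimulus is represented, infers monosynaptic
connectivity between simultaneously recorded units, and simulates spike
transmission through converging connections.

## What it computes

For a unit with spike times T_i over N repeated trials of the standardized
stimulus z(t):

* **Decoding quality Q** — reconstruct the stimulus by convolving each
  held-out trial's spikes with a cross-validated filter (spike-triggered
  average S = ⟨z(T_i + τ)⟩ for τ ∈ [−50, 50] ms; its signal-whitened
  variant; or the modified Wiener filter w = A⁻¹s, the STA deconvolved by
  the Toeplitz matrix A of the spike-train autocorrelation — twelve models
  in causal/acausal and ISI-conditional variants). Q is the trial-averaged
  Spearman correlation ρ(z, ẑ_i); significance comes from within-trial
  spike-time shuffles (geometric-mean p).
* **Precision P** — the smallest interval-jitter half-window δ (log-spaced
  0.4–102.4 ms, plus a focused sweep) whose application consistently
  degrades Q (one-tailed Wilcoxon rank-sum on per-trial q, p < 0.05).
* **Reliability timescale Rp** — smooth each trial with a Gaussian kernel
  of SD σ; reliability r(σ) is the mean trial-pair correlation; Rp is the
  σ maximizing the profile. Units are classed as *rate* coders (profile
  rising to the largest σ), *temporal* coders (consistent interior peak),
  or *undefined*.
* **Spike transmission** — from cross-correlograms (0.4 ms bins) in
  stimulus-free epochs: a deconvolved, baseline-subtracted transmission
  curve whose area over the monosynaptic peak (0 < t ≤ 5 ms, extended to
  its zero crossings) is the transmission *gain* (excess postsynaptic
  spikes per presynaptic spike), with a Bonferroni-corrected Poisson
  detector at α = 0.001.
* **Transmission models** — synthetic postsynaptic trains built from
  presynaptic trains under labeled-line (LL), summed-population (SP), or
  coincidence-detection rules (CD1: y = Π(x_i + γ) − γⁿ; CD2:
  y = Σx_i · γ^(n−1)), with background spikes equalizing the firing rate.

A seedable point-process simulator (signal + noise mother trains,
per-trial daughters with Gaussian jitter and random spike addition or
removal) generates ground-truth data for all of the above. See
`docs/methods.md` for the models, estimators, and numerical choices.

## Worked example

```python
from wnspike import (generate_wn_signal, standardize, SimulationConfig,
                     simulate_unit, crossval_decode)
from wnspike.precision import precision_sweep
from wnspike.reliability import reliability_profile

# the fixed 1 s stimulus, standardized on the 2.5 kHz analysis grid
stim = standardize(generate_wn_signal(duration=1.0, fs=6000.0, tau=3.0, seed=7)
                   .resample(2500.0))

# a unit firing at ~100 spikes/s, spike times jittered by 2 ms across
# trials, with up to 10 spikes added/removed per trial
cfg = SimulationConfig(lambda1=100.0, sigma1=2.0, n_add=10, seed=11)
unit = simulate_unit(cfg, stim, unit_id="demo")

decoding = crossval_decode(stim, unit, kind="mwiener", n_shuffles=100, seed=1)
print(f"Q = {decoding.Q:.3f}   p = {decoding.p_overall:.4f}   "
      f"time lag = {decoding.time_lag_ms:.1f} ms")

prec = precision_sweep(stim, unit, kind="mwiener", seed=1, decoding=decoding)
print(f"precision P = {prec.P_ms:.2f} ms")

prof = reliability_profile(unit)
print(f"reliability timescale Rp = {prof.Rp_ms:.1f} ms   class = {prof.coder_class}")
```

prints

```
Q = 0.490   p = 0.0099   time lag = -0.8 ms
precision P = 1.50 ms
reliability timescale Rp = 9.3 ms   class = temporal
```

The unit decodes the stimulus well above chance (Q = 0.49, shuffle
p < 0.05); its near-zero time lag reflects the simulator's lag-free drive
kernel. The recovered precision (1.5 ms) sits within a factor of two of
the injected 2 ms jitter, and the added/removed spikes produce an interior
reliability peak near 9 ms — a temporal coder.

A thin CLI wraps the same pipeline (`wnspike simulate|decode|precision|
reliability|connectivity|sint|screen|report`), reading and writing
plain-text tables (TSV spike tables and signals, JSON reports).

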