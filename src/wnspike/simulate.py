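"""Point-process simulation of white-noise-driven spike trains.

A unit is modelled as the superposition of a *signal* train, whose rate is
the stimulus convolved with a simplified STA-like kernel (one cycle of a
100 Hz sinusoid), and a *noise* train with a homogeneous rate.  A single
"mother" train of each kind is sampled per unit, then replicated into N
per-trial "daughter" trains, each independently degraded by Gaussian spike
jitter, random spike removal and random spike addition.  Signal jitter
controls timing precision; noise rate and noise jitter control the
reliability timescale.

Times are milliseconds relative to trial onset throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._core import derive_rng
from .signal import StimulusTrace

__all__ = [
    "SimulationConfig",
    "SpikeTrainSet",
    "rate_from_signal",
    "sample_poisson_train",
    "make_daughter_trains",
    "simulate_unit",
]

# stream role codes for independent PRNG substreams
_ROLE_SIGNAL_MOTHER = 1
_ROLE_NOISE_MOTHER = 2
_ROLE_SIGNAL_DAUGHTER = 3
_ROLE_NOISE_DAUGHTER = 4


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the per-unit point-process simulation.

    Defaults are the simulation's standard conditions: 2500 Hz grid, 25
    trials of 1 s, a one-cycle 100 Hz STA-like kernel, and a 2 ms minimum
    inter-spike interval imposed on the mother trains.
    """

    fs: float = 2500.0
    n_trials: int = 25
    duration: float = 1.0  # seconds
    lambda1: float = 100.0  # signal rate, spikes/s
    sigma1: float = 3.0  # signal jitter SD, ms
    lambda2: float = 0.0  # noise rate, spikes/s
    sigma2: float = 0.0  # noise jitter SD, ms
    n_add: int = 0  # max spikes added per daughter
    n_remove: int = -1  # max spikes removed; -1 means "equal to n_add"
    min_isi: float = 2.0  # ms, imposed on mother trains only
    kernel_freq: float = 100.0  # Hz, STA-like kernel frequency
    seed: int = 0

    def __post_init__(self):
        if self.n_remove == -1:
            object.__setattr__(self, "n_remove", self.n_add)
        if self.n_remove != self.n_add:
            raise ValueError("n_remove must equal n_add")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("rates must be non-negative")
        if self.min_isi < 0 or self.n_trials < 1:
            raise ValueError("min_isi must be >= 0 and n_trials >= 1")


@dataclass
class SpikeTrainSet:
    """Trial-aligned spike times of one unit over N repeated identical trials.

    ``trials`` is a list of sorted float arrays of spike times in ms, each in
    ``[0, duration_ms)``.
    """

    unit_id: str
    trials: list[np.ndarray]
    duration_ms: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.trials = [np.asarray(t, dtype=np.float64) for t in self.trials]
        for t in self.trials:
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ValueError("trial spike times must be strictly increasing")
            if len(t) and (t[0] < 0 or t[-1] >= self.duration_ms):
                raise ValueError("spike times must lie in [0, duration)")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_spikes(self) -> int:
        return int(sum(len(t) for t in self.trials))

    def mean_rate(self) -> float:
        """Mean firing rate in spikes/s over all trials."""
        return self.n_spikes / (self.n_trials * self.duration_ms / 1000.0)

    def pooled(self) -> np.ndarray:
        """All spike times concatenated on a common absolute axis, trial k
        offset by ``k * duration_ms`` (for autocorrelation analyses)."""
        return np.concatenate(
            [t + k * self.duration_ms for k, t in enumerate(self.trials)]
        ) if self.trials else np.empty(0)


def sine_cycle_kernel(kernel_freq: float, fs: float) -> np.ndarray:
    """One full cycle of ``sin(2*pi*f*t)`` sampled at ``fs`` (the simplified
    STA-like template; 25 samples at 100 Hz / 2500 Hz)."""
    if kernel_freq <= 0:
        raise ValueError("kernel_freq must be positive")
    n = int(round(fs / kernel_freq))
    t = np.arange(n) / fs
    return np.sin(2.0 * np.pi * kernel_freq * t)


def rate_from_signal(trace: StimulusTrace, kernel_freq: float, lambda1: float) -> np.ndarray:
    """Firing-rate profile f(t): the standardized stimulus convolved with one
    sinusoid cycle, rectified, and scaled so its time average is ``lambda1``.

    Returns spikes/s per sample on the trace's grid.
    """
    if lambda1 < 0:
        raise ValueError("lambda1 must be non-negative")
    if not trace.standardized:
        raise ValueError("rate_from_signal requires a standardized trace")
    k = sine_cycle_kernel(kernel_freq, trace.fs)
    # causal convolution: the rate at t is driven by the signal up to one
    # kernel length in the past, so spikes follow the stimulus feature
    f = np.convolve(trace.samples, k, mode="full")[: len(trace.samples)]
    np.clip(f, 0.0, None, out=f)
    m = f.mean()
    if m > 0:
        f *= lambda1 / m
    return f


def sample_poisson_train(
    rate: np.ndarray,
    fs: float,
    min_isi: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample a spike train from a discretized non-homogeneous Poisson process.

    At each time step a spike occurs with probability ``rate/fs`` (Bernoulli);
    probabilities above 1 are clipped.  A minimum inter-spike interval is then
    imposed causally: a spike closer than ``min_isi`` ms to the last *retained*
    spike is deleted.

    Returns sorted spike times in ms.
    """
    p = np.asarray(rate, dtype=np.float64) / fs
    np.clip(p, 0.0, 1.0, out=p)
    hits = np.nonzero(rng.random(len(p)) < p)[0]
    times = hits / fs * 1000.0
    if min_isi > 0 and len(times) > 1:
        keep = [0]
        last = times[0]
        for i in range(1, len(times)):
            if times[i] - last >= min_isi:
                keep.append(i)
                last = times[i]
        times = times[keep]
    return times


def make_daughter_trains(
    mother: np.ndarray,
    n_trials: int,
    jitter_sd: float,
    n_remove: int,
    n_add: int,
    duration_ms: float,
    rng: np.random.Generator,
    fs: float = 2500.0,
) -> list[np.ndarray]:
    """Replicate a mother train into jittered/degraded per-trial daughters.

    Per daughter: every spike is shifted by an independent N(0, jitter_sd)
    draw and clipped to [0, duration); then ``k_rm ~ Uniform{0..n_remove}``
    spikes are removed uniformly at random; then ``k_ad ~ Uniform{0..n_add}``
    spikes are added at uniform times.  Duplicate times are perturbed by half
    a sample so trains stay strictly increasing.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    if n_remove < 0 or n_add < 0:
        raise ValueError("n_remove and n_add must be non-negative")
    mother = np.asarray(mother, dtype=np.float64)
    eps = 0.5 / fs * 1000.0  # half a sample, ms
    hi = np.nextafter(duration_ms, 0.0)
    daughters = []
    for _ in range(n_trials):
        t = mother.copy()
        if jitter_sd > 0 and len(t):
            t = t + rng.normal(0.0, jitter_sd, size=len(t))
            np.clip(t, 0.0, hi, out=t)
        if n_remove > 0 and len(t):
            k_rm = min(int(rng.integers(0, n_remove + 1)), len(t))
            if k_rm:
                drop = rng.choice(len(t), size=k_rm, replace=False)
                t = np.delete(t, drop)
        if n_add > 0:
            k_ad = int(rng.integers(0, n_add + 1))
            if k_ad:
                t = np.concatenate([t, rng.uniform(0.0, duration_ms, size=k_ad)])
        t.sort()
        # break exact ties by nudging later duplicates forward half a sample
        while len(t) > 1 and np.any(np.diff(t) <= 0):
            dup = np.nonzero(np.diff(t) <= 0)[0] + 1
            t[dup] += eps
            np.clip(t, 0.0, hi, out=t)
            t.sort()
            t = np.unique(t)
        daughters.append(t)
    return daughters


def simulate_unit(cfg: SimulationConfig, trace: StimulusTrace, unit_id: str = "sim") -> SpikeTrainSet:
    """Simulate one unit: signal + noise mothers, N degraded daughters each,
    merged per trial.

    ``trace`` must be standardized and on the simulation grid (``cfg.fs``).
    """
    if abs(trace.fs - cfg.fs) > 1e-9:
        raise ValueError(f"trace is sampled at {trace.fs} Hz, config expects {cfg.fs}")
    dur_ms = cfg.duration * 1000.0
    n_samp = int(round(cfg.duration * cfg.fs))
    if len(trace.samples) < n_samp:
        raise ValueError("trace shorter than the configured duration")

    f_sig = rate_from_signal(trace, cfg.kernel_freq, cfg.lambda1)[:n_samp]
    mother_sig = sample_poisson_train(
        f_sig, cfg.fs, cfg.min_isi, derive_rng(cfg.seed, _ROLE_SIGNAL_MOTHER)
    )
    f_noise = np.full(n_samp, cfg.lambda2)
    mother_noise = sample_poisson_train(
        f_noise, cfg.fs, cfg.min_isi, derive_rng(cfg.seed, _ROLE_NOISE_MOTHER)
    )

    d_sig = make_daughter_trains(
        mother_sig, cfg.n_trials, cfg.sigma1, cfg.n_remove, cfg.n_add, dur_ms,
        derive_rng(cfg.seed, _ROLE_SIGNAL_DAUGHTER), fs=cfg.fs,
    )
    d_noise = make_daughter_trains(
        mother_noise, cfg.n_trials, cfg.sigma2, cfg.n_remove, cfg.n_add, dur_ms,
        derive_rng(cfg.seed, _ROLE_NOISE_DAUGHTER), fs=cfg.fs,
    )

    eps = 0.5 / cfg.fs * 1000.0
    hi = np.nextafter(dur_ms, 0.0)
    trials = []
    for a, b in zip(d_sig, d_noise):
        t = np.concatenate([a, b])
        t.sort()
        while len(t) > 1 and np.any(np.diff(t) <= 0):
            dup = np.nonzero(np.diff(t) <= 0)[0] + 1
            t[dup] += eps
            np.clip(t, 0.0, hi, out=t)
            t.sort()
            t = np.unique(t)
        trials.append(t)
    meta = {
        "config": cfg,
        "n_mother_signal": len(mother_sig),
        "n_mother_noise": len(mother_noise),
    }
    return SpikeTrainSet(unit_id=unit_id, trials=trials, duration_ms=dur_ms, meta=meta)


def bin_spikes(times_ms: np.ndarray, fs: float, n_samples: int) -> np.ndarray:
    """Bin spike times (ms) onto the analysis grid as a count vector."""
    idx = np.round(np.asarray(times_ms) * fs / 1000.0).astype(np.intp)
    np.clip(idx, 0, n_samples - 1, out=idx)
    out = np.zeros(n_samples)
    np.add.at(out, idx, 1.0)
    return out
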