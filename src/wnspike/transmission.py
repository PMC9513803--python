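"""Synthetic postsynaptic spike trains under transmission models.

A postsynaptic interneuron's drive is modelled from its presynaptic
pyramidal-cell spike trains: each presynaptic train is convolved with that
pair's spike-transmission curve to give a rate function x_i(t).  The rates
are combined under one of four rules —

* **LL** (labeled line): a single input, y = x.
* **SP** (summed population): linear summation, y = Σ x_i.
* **CD1** (synaptic multiplication): with n(t) active inputs,
  y = Π(x_i + γ) − γ^n for n > 1, y = x_i for n = 1, y = 0 for n = 0.
* **CD2** (nonlinear summation): y = (Σ x_i) · γ^(n−1) for n ≥ 1, else 0.

Isolated presynaptic spikes are never amplified; coincident spikes are
amplified supralinearly (γ is a non-negative nonlinearity factor with rate
units in CD1 and dimensionless in CD2).  A synthetic train (ST1) is sampled
from y(t); background spikes are added to equalize the mean rate with the
target's observed rate FR_WN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._core import derive_rng
from .connectivity import TransmissionCurve
from .simulate import SpikeTrainSet, sample_poisson_train

__all__ = [
    "SINTConfig",
    "presyn_rate",
    "combine_ll",
    "combine_sp",
    "combine_cd1",
    "combine_cd2",
    "combine_rates",
    "generate_sint",
    "MODELS",
]

MODELS = ("LL", "SP", "CD1", "CD2")


@dataclass(frozen=True)
class SINTConfig:
    """Configuration of one synthetic-interneuron generation run."""

    model: str
    fr_wn: float  # target mean rate during stimulation, spikes/s
    gamma: float = 0.0  # CD nonlinearity factor
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if not self.noiseless and self.fr_wn <= 0:
            raise ValueError("fr_wn must be positive unless noiseless")


def presyn_rate(
    pre_trials: list[np.ndarray],
    curve: TransmissionCurve,
    fs: float,
    n_samples: int,
) -> np.ndarray:
    """Per-trial rate function x_i(t): presynaptic spikes convolved with the
    causal part of the pair's transmission curve.

    Only strictly positive lags of the curve are used and negative excess is
    clipped to zero, so the rate is non-negative and strictly causal.
    Returns an (n_trials, n_samples) array in spikes/s.
    """
    causal = curve.lags_ms > 0
    lags = curve.lags_ms[causal]
    vals = np.clip(curve.excess_rate[causal], 0.0, None)
    lag_idx = np.round(lags * fs / 1000.0).astype(np.intp)
    L = int(lag_idx.max()) + 1 if len(lag_idx) else 1
    kernel = np.zeros(L)
    np.add.at(kernel, lag_idx, vals)
    out = np.zeros((len(pre_trials), n_samples))
    for k, t in enumerate(pre_trials):
        idx = np.clip(np.round(np.asarray(t) * fs / 1000.0).astype(np.intp), 0, n_samples - 1)
        for i in idx:
            hi = min(i + L, n_samples)
            out[k, i:hi] += kernel[: hi - i]
    return out


def combine_ll(xs: np.ndarray) -> np.ndarray:
    """Labeled line: identity on a single presynaptic rate function."""
    xs = np.atleast_2d(np.asarray(xs, dtype=np.float64))
    if xs.shape[0] != 1:
        raise ValueError("LL takes exactly one presynaptic input")
    return xs[0].copy()


def combine_sp(xs: np.ndarray) -> np.ndarray:
    """Summed population: elementwise sum of the presynaptic rates."""
    xs = np.atleast_2d(np.asarray(xs, dtype=np.float64))
    return xs.sum(axis=0)


def _active(xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    act = xs > 0
    return act, act.sum(axis=0)


def combine_cd1(xs: np.ndarray, gamma: float) -> np.ndarray:
    """Synaptic-multiplication coincidence detection.

    Per sample: 0 when no input is active; the single active x_i when one
    is; Π over *active* inputs of (x_i + γ) minus γ^n when n > 1.  Products
    run over active inputs only, which makes the n = 1 and n = 0 special
    cases the continuous limits of the general formula.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    xs = np.atleast_2d(np.asarray(xs, dtype=np.float64))
    act, n = _active(xs)
    prod = np.prod(np.where(act, xs + gamma, 1.0), axis=0)
    y = np.where(n > 0, prod - gamma ** n.astype(float), 0.0)
    # n == 1 reduces to the active input exactly even when gamma > 0
    single = n == 1
    if np.any(single):
        y[single] = xs.T[single][act.T[single]]
    return np.clip(y, 0.0, None)


def combine_cd2(xs: np.ndarray, gamma: float) -> np.ndarray:
    """Nonlinear-summation coincidence detection:
    y = (Σ active x_i) · γ^(n−1) for n ≥ 1, 0 otherwise.  γ = 1 reduces to
    SP; a single active input passes through unamplified."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    xs = np.atleast_2d(np.asarray(xs, dtype=np.float64))
    act, n = _active(xs)
    s = np.where(act, xs, 0.0).sum(axis=0)
    y = np.where(n > 0, s * gamma ** np.maximum(n - 1, 0).astype(float), 0.0)
    return y


def combine_rates(xs: np.ndarray, model: str, gamma: float = 0.0) -> np.ndarray:
    """Dispatch to the requested combination rule."""
    if model == "LL":
        return combine_ll(xs)
    if model == "SP":
        return combine_sp(xs)
    if model == "CD1":
        return combine_cd1(xs, gamma)
    if model == "CD2":
        return combine_cd2(xs, gamma)
    raise ValueError(f"unknown model {model!r}")


def generate_sint(
    rate_trials: np.ndarray,
    fs: float,
    duration_ms: float,
    cfg: SINTConfig,
    unit_id: str = "sint",
) -> SpikeTrainSet:
    """Sample a synthetic postsynaptic train from per-trial rate functions.

    ST1 is drawn per trial with the simulator's per-sample binomial scheme
    (no minimum ISI).  Its realized mean rate FR1 is measured; if FR1 is
    below the target FR_WN (and the run is not noiseless), homogeneous
    Poisson background at FR2 = FR_WN − FR1 is merged in so the synthetic
    unit matches the target's overall rate.
    """
    rate_trials = np.atleast_2d(np.asarray(rate_trials, dtype=np.float64))
    n_trials, n_samples = rate_trials.shape
    total_s = n_trials * n_samples / fs
    rng_sig = derive_rng(cfg.seed, 31)
    rng_bg = derive_rng(cfg.seed, 32)
    st1 = [sample_poisson_train(r, fs, 0.0, rng_sig) for r in rate_trials]
    fr1 = sum(len(t) for t in st1) / total_s
    trials = st1
    fr2 = 0.0
    if not cfg.noiseless and fr1 < cfg.fr_wn:
        fr2 = cfg.fr_wn - fr1
        bg_rate = np.full(n_samples, fr2)
        trials = []
        for t in st1:
            bg = sample_poisson_train(bg_rate, fs, 0.0, rng_bg)
            m = np.concatenate([t, bg])
            m.sort()
            # nudge exact collisions forward by half a sample
            eps = 0.5 / fs * 1000.0
            while len(m) > 1 and np.any(np.diff(m) <= 0):
                dup = np.nonzero(np.diff(m) <= 0)[0] + 1
                m[dup] += eps
                np.clip(m, 0.0, np.nextafter(duration_ms, 0.0), out=m)
                m.sort()
                m = np.unique(m)
            trials.append(m)
    meta = {"model": cfg.model, "gamma": cfg.gamma, "fr_wn": cfg.fr_wn,
            "fr1": fr1, "fr2": fr2, "noiseless": cfg.noiseless, "seed": cfg.seed}
    return SpikeTrainSet(unit_id=unit_id, trials=trials, duration_ms=duration_ms, meta=meta)
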