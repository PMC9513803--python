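"""Filter models and cross-validated stimulus reconstruction.

A unit's spikes are used to build a reconstruction filter — spike-triggered
average (STA), signal-whitened STA ("Wiener"), or STA deconvolved by the
spike-train autocorrelation ("modified Wiener") — in causal and acausal
variants, each optionally conditioned on the preceding inter-spike interval
(a bank of ten decile filters).  Filters are fit on 90% of trials and used
to reconstruct the stimulus from the held-out trials (10-fold
cross-validation).  Decoding quality Q is the trial-averaged Spearman rank
correlation between the standardized stimulus z(t) and the reconstruction;
significance comes from within-trial spike-time shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import linalg

from ._core import derive_rng, standardized_ranks, toeplitz_solve
from .signal import StimulusTrace
from .simulate import SpikeTrainSet

__all__ = [
    "FilterModel",
    "DecodingResult",
    "FittedDecoder",
    "compute_sta",
    "make_causal",
    "conditional_filter_bank",
    "whiten_signal",
    "modified_wiener",
    "spike_train_ach",
    "fit_filter",
    "fit_decoder",
    "crossval_decode",
    "MODEL_KINDS",
]

#: the six base filter kinds; with the causal flag they form the twelve
#: cross-validated reconstruction models.  "pwsta" shares the Wiener filter
#: but gauges the reconstruction against the *whitened* stimulus.
MODEL_KINDS = ("sta", "csta", "wiener", "cwiener", "mwiener", "cmwiener", "pwsta")

_CONDITIONAL = {"csta", "cwiener", "cmwiener"}


class InsufficientDataError(ValueError):
    """Raised when there are too few spikes to build the requested filter."""


@dataclass(frozen=True)
class FilterModel:
    """A reconstruction filter (or ISI-conditional filter bank).

    ``coefficients`` has shape (n_lags,) for simple filters and
    (n_bins, n_lags) for conditional banks.  ``lags_ms`` spans [-window,
    +window] symmetrically; causal filters are exactly zero at positive lags.
    """

    kind: str
    causal: bool
    lags_ms: np.ndarray
    coefficients: np.ndarray
    fs: float
    isi_bin_edges: np.ndarray | None = None  # 11 edges for conditional banks

    def __post_init__(self):
        object.__setattr__(self, "lags_ms", np.asarray(self.lags_ms, dtype=np.float64))
        object.__setattr__(self, "coefficients", np.asarray(self.coefficients, dtype=np.float64))

    @property
    def is_bank(self) -> bool:
        return self.coefficients.ndim == 2

    @property
    def half_len(self) -> int:
        return (len(self.lags_ms) - 1) // 2

    def peak_lag_ms(self) -> float:
        """Lag of the largest coefficient (bank rows averaged)."""
        c = self.coefficients.mean(axis=0) if self.is_bank else self.coefficients
        return float(self.lags_ms[int(np.argmax(c))])


@dataclass
class DecodingResult:
    """Cross-validated decoding quality of one unit under one filter model.

    ``Q`` is the mean of the per-trial rank correlations ``q_trials`` (NaN
    entries are zero-spike trials, excluded); ``p_overall`` is the geometric
    mean of the per-trial shuffle p values.  ``time_lag_ms`` is positive when
    the signal precedes the spikes.
    """

    unit_id: str
    kind: str
    causal: bool
    q_trials: np.ndarray
    Q: float
    p_trials: np.ndarray | None
    p_overall: float | None
    time_lag_ms: float
    filter: FilterModel
    n_folds: int
    n_excluded: int = 0
    residual: float | None = None


# ---------------------------------------------------------------------------
# filter construction
# ---------------------------------------------------------------------------

def _segments(z: np.ndarray, idx: np.ndarray, half: int) -> np.ndarray:
    """Zero-padded segments z[i-half .. i+half] for each spike index."""
    zp = np.concatenate([np.zeros(half), z, np.zeros(half)])
    cols = idx[:, None] + np.arange(2 * half + 1)[None, :]
    return zp[cols]


def _spike_indices(times_ms: Sequence[np.ndarray], fs: float, n: int) -> list[np.ndarray]:
    out = []
    for t in times_ms:
        idx = np.round(np.asarray(t) * fs / 1000.0).astype(np.intp)
        out.append(np.clip(idx, 0, n - 1))
    return out


def compute_sta(trace: StimulusTrace, trains: SpikeTrainSet, window: float = 50.0) -> FilterModel:
    """Spike-triggered average: the mean standardized-stimulus segment in a
    ±``window`` ms window around every spike (edge segments zero-padded)."""
    if not trace.standardized:
        raise ValueError("compute_sta requires the standardized stimulus")
    z = trace.samples
    half = int(round(window * trace.fs / 1000.0))
    idx = np.concatenate(_spike_indices(trains.trials, trace.fs, len(z)))
    if len(idx) == 0:
        raise InsufficientDataError("no spikes available for the STA")
    coef = _segments(z, idx, half).mean(axis=0)
    lags = (np.arange(-half, half + 1)) / trace.fs * 1000.0
    return FilterModel(kind="sta", causal=False, lags_ms=lags, coefficients=coef, fs=trace.fs)


def make_causal(filt: FilterModel) -> FilterModel:
    """Zero the coefficients at strictly positive lags (idempotent)."""
    c = filt.coefficients.copy()
    pos = filt.lags_ms > 0
    if c.ndim == 2:
        c[:, pos] = 0.0
    else:
        c[pos] = 0.0
    return replace(filt, causal=True, coefficients=c)


def _isi_tags(trains: SpikeTrainSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-spike preceding ISI (ms), pooled over trials.

    A trial's first spike takes the ISI to the last spike of the previous
    trial (wrapping across the inter-trial gap) when one exists; otherwise
    the ISI is NaN and the spike is later assigned the top decile.
    Returns (pooled ISIs, trial index of each spike).
    """
    isis, trial_of = [], []
    prev_last = None
    for k, t in enumerate(trains.trials):
        if len(t) == 0:
            prev_last = None if prev_last is None else prev_last
            continue
        d = np.empty(len(t))
        d[1:] = np.diff(t)
        if prev_last is not None:
            d[0] = t[0] + (trains.duration_ms - prev_last)
        else:
            d[0] = np.nan
        isis.append(d)
        trial_of.append(np.full(len(t), k, dtype=np.intp))
        prev_last = t[-1]
    if not isis:
        raise InsufficientDataError("no spikes available")
    return np.concatenate(isis), np.concatenate(trial_of)


def _isi_bin_of(isis: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Decile index of each ISI given 11 edges; NaN ISIs go to the top bin."""
    n_bins = len(edges) - 1
    bins = np.searchsorted(edges, isis, side="right") - 1
    bins = np.clip(bins, 0, n_bins - 1)
    bins[np.isnan(isis)] = n_bins - 1
    return bins


def conditional_filter_bank(
    trace: StimulusTrace, trains: SpikeTrainSet, n_bins: int = 10, window: float = 50.0
) -> FilterModel:
    """ISI-conditional STA bank: spikes are tagged by the decile of their
    preceding inter-spike interval and a separate STA is built per decile."""
    if not trace.standardized:
        raise ValueError("conditional_filter_bank requires the standardized stimulus")
    z = trace.samples
    half = int(round(window * trace.fs / 1000.0))
    isis, _ = _isi_tags(trains)
    idx = np.concatenate(_spike_indices(trains.trials, trace.fs, len(z)))
    finite = isis[np.isfinite(isis)]
    if len(finite) < n_bins:
        raise InsufficientDataError("too few ISIs for the conditional bank")
    edges = np.quantile(finite, np.linspace(0.0, 1.0, n_bins + 1))
    if len(np.unique(edges)) < n_bins + 1:
        raise InsufficientDataError("tied ISI deciles give degenerate bin edges")
    bins = _isi_bin_of(isis, edges)
    segs = _segments(z, idx, half)
    bank = np.zeros((n_bins, 2 * half + 1))
    for b in range(n_bins):
        sel = bins == b
        if not np.any(sel):
            raise InsufficientDataError(f"ISI decile {b} is empty")
        bank[b] = segs[sel].mean(axis=0)
    lags = (np.arange(-half, half + 1)) / trace.fs * 1000.0
    return FilterModel(
        kind="csta", causal=False, lags_ms=lags, coefficients=bank, fs=trace.fs,
        isi_bin_edges=edges,
    )


def whiten_signal(
    trace: StimulusTrace, var_fraction: float = 0.9, window: float = 50.0
) -> tuple[StimulusTrace, np.ndarray]:
    """Whiten a signal by the pseudo square-root inverse of its lag-window
    Toeplitz autocovariance.

    The autocovariance (biased estimator) over lags up to the full filter
    window is eigendecomposed; the smallest leading set of eigenvalues whose
    cumulative share reaches ``var_fraction`` is retained, the rest are
    dropped from the pseudo-inverse to avoid amplifying high-frequency noise.
    The resulting symmetric operator W = V Λ_r^{-1/2} Vᵀ is applied to the
    series as an FIR filter (its center row).

    Returns the whitened trace and the whitening matrix W.
    """
    z = np.asarray(trace.samples, dtype=np.float64)
    half = int(round(window * trace.fs / 1000.0))
    dim = 2 * half + 1
    n = len(z)
    zc = z - z.mean()
    acov = np.array([zc[: n - k] @ zc[k:] / n for k in range(dim)])
    C = linalg.toeplitz(acov)
    w, V = linalg.eigh(C)
    w = np.maximum(w, 0.0)  # floor tiny negative numerical eigenvalues
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    cum = np.cumsum(w) / w.sum()
    k = int(np.searchsorted(cum, var_fraction - 1e-12) + 1)
    k = min(k, dim)
    inv_sqrt = np.zeros(dim)
    inv_sqrt[:k] = 1.0 / np.sqrt(w[:k])
    W = (V * inv_sqrt[None, :]) @ V.T
    h = W[half]
    y = np.convolve(z, h, mode="full")[half : half + n]
    return replace(trace, samples=y), W


def spike_train_ach(trains: SpikeTrainSet, fs: float, window: float = 50.0) -> np.ndarray:
    """Per-spike-normalized autocorrelation histogram over ±``window`` ms on
    the analysis grid (bin = 1/fs).

    Distinct within-trial spike pairs are counted per lag bin and divided by
    the number of spikes; the zero-lag bin additionally carries the
    self-coincidence of every spike (value 1), which makes the Toeplitz
    deconvolution operator identity-like for a Poisson train and keeps it
    well conditioned.
    """
    half = int(round(window * fs / 1000.0))
    counts = np.zeros(2 * half + 1)
    n_spk = 0
    bin_ms = 1000.0 / fs
    for t in trains.trials:
        n_spk += len(t)
        if len(t) < 2:
            continue
        for i, ti in enumerate(t):
            lo = np.searchsorted(t, ti - (half + 0.5) * bin_ms)
            hi = np.searchsorted(t, ti + (half + 0.5) * bin_ms)
            d = t[lo:hi] - ti
            k = np.round(d / bin_ms).astype(np.intp) + half
            np.clip(k, 0, 2 * half, out=k)
            np.add.at(counts, k, 1.0)
        counts[half] -= len(t)  # remove self pairs from the raw histogram
    if n_spk == 0:
        raise InsufficientDataError("no spikes for the autocorrelation histogram")
    ach = counts / n_spk
    ach[half] += 1.0  # self-coincidence term
    return ach


def modified_wiener(
    sta: FilterModel, trains: SpikeTrainSet, eig_floor: float = 1e-6
) -> FilterModel:
    """Deconvolve the spike-train autocorrelation from the STA:
    solve A w = s with A the symmetric Toeplitz matrix of the ACH.

    The solve uses a regularized eigendecomposition (eigenvalues floored at
    ``eig_floor`` times the maximum).  The relative residual ||A w - s||/||s||
    is not stored on the filter but can be recomputed; it is reported by
    :func:`fit_filter` callers that need it.
    """
    # the convolution operator (A w)(tau) needs the ACH out to twice the
    # filter window: lags |tau - tau'| run up to 2 * window
    window = float(sta.lags_ms[-1])
    ach = spike_train_ach(trains, sta.fs, window=2.0 * window)
    mid = (len(ach) - 1) // 2
    first_col = ach[mid : mid + 2 * sta.half_len + 1]
    if sta.is_bank:
        coef = np.vstack([toeplitz_solve(first_col, row, eig_floor) for row in sta.coefficients])
    else:
        coef = toeplitz_solve(first_col, sta.coefficients, eig_floor)
    return replace(sta, kind="mwiener" if not sta.is_bank else "cmwiener", coefficients=coef)


def fit_filter(
    trace: StimulusTrace,
    trains: SpikeTrainSet,
    kind: str,
    causal: bool = False,
    window: float = 50.0,
    var_fraction: float = 0.9,
) -> FilterModel:
    """Build one of the reconstruction filters on the full provided data.

    ``kind`` is one of ``MODEL_KINDS``; "pwsta" uses the same filter as
    "wiener" (the two differ only in the signal the reconstruction is gauged
    against during decoding).
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    conditional = kind in _CONDITIONAL
    if kind in ("wiener", "cwiener", "pwsta"):
        base_trace, _ = whiten_signal(trace, var_fraction=var_fraction, window=window)
    else:
        base_trace = trace
    if conditional:
        filt = conditional_filter_bank(base_trace, trains, window=window)
    else:
        filt = compute_sta(base_trace, trains, window=window)
    if kind in ("mwiener", "cmwiener"):
        filt = modified_wiener(filt, trains)
    filt = replace(filt, kind=kind)
    if causal:
        filt = make_causal(filt)
    return filt


# ---------------------------------------------------------------------------
# reconstruction and cross-validated decoding
# ---------------------------------------------------------------------------

def reconstruct_trial(
    filt: FilterModel, times_ms: np.ndarray, n_samples: int, prev_last_ms: float | None = None,
    duration_ms: float | None = None,
) -> np.ndarray:
    """Reconstruction ẑ(t) = Σ_j c(t - T_j): place the filter at every spike.

    For conditional banks every spike is convolved with the row of its ISI
    decile (the bank's stored edges); a first spike with no available
    preceding ISI uses the top decile.
    """
    half = filt.half_len
    y = np.zeros(n_samples + 2 * half)
    idx = np.clip(np.round(np.asarray(times_ms) * filt.fs / 1000.0).astype(np.intp), 0, n_samples - 1)
    if not filt.is_bank:
        c = filt.coefficients
        for i in idx:
            y[i : i + 2 * half + 1] += c
    else:
        t = np.asarray(times_ms)
        d = np.empty(len(t))
        if len(t):
            d[1:] = np.diff(t)
            if prev_last_ms is not None and duration_ms is not None:
                d[0] = t[0] + (duration_ms - prev_last_ms)
            else:
                d[0] = np.nan
        bins = _isi_bin_of(d, filt.isi_bin_edges)
        for b, i in zip(bins, idx):
            y[i : i + 2 * half + 1] += filt.coefficients[b]
    return y[half : half + n_samples]


@dataclass
class FittedDecoder:
    """Per-fold filters plus everything needed to score (possibly jittered)
    test-set spike trains without refitting."""

    trace: StimulusTrace  # standardized signal on the analysis grid
    trains: SpikeTrainSet
    kind: str
    causal: bool
    n_folds: int
    fold_of_trial: np.ndarray  # fold index per trial
    filters: list[FilterModel]  # one per fold
    full_filter: FilterModel  # fit on all trials (reported peak lag)
    gauge_ranks: np.ndarray  # standardized ranks of the gauged signal
    n_samples: int

    def trial_q(self, trial_idx: int, times_ms: np.ndarray) -> float:
        """Rank correlation of the reconstruction of one trial's spikes with
        the gauged stimulus, using that trial's held-out fold filter.
        Returns NaN for an empty train."""
        if len(times_ms) == 0:
            return np.nan
        filt = self.filters[self.fold_of_trial[trial_idx]]
        prev = None
        if trial_idx > 0 and len(self.trains.trials[trial_idx - 1]):
            prev = self.trains.trials[trial_idx - 1][-1]
        zhat = reconstruct_trial(filt, times_ms, self.n_samples, prev, self.trains.duration_ms)
        return float(standardized_ranks(zhat) @ self.gauge_ranks)

    def all_q(self, trials: Sequence[np.ndarray] | None = None) -> np.ndarray:
        trials = self.trains.trials if trials is None else trials
        return np.array([self.trial_q(i, t) for i, t in enumerate(trials)])


def _subset(trains: SpikeTrainSet, keep: np.ndarray) -> SpikeTrainSet:
    return SpikeTrainSet(
        unit_id=trains.unit_id,
        trials=[trains.trials[i] for i in keep],
        duration_ms=trains.duration_ms,
    )


def fit_decoder(
    trace: StimulusTrace,
    trains: SpikeTrainSet,
    kind: str = "mwiener",
    causal: bool = False,
    n_folds: int = 10,
    window: float = 50.0,
    var_fraction: float = 0.9,
) -> FittedDecoder:
    """Fit the 10-fold cross-validated filter set for one unit.

    Trials are partitioned into ``n_folds`` contiguous folds; the filter of a
    fold is fit on all other trials.  The gauged signal is the standardized
    stimulus, except for "pwsta" where it is the whitened stimulus.
    """
    if trains.n_trials < n_folds or n_folds < 2:
        raise ValueError("need n_trials >= n_folds >= 2")
    if abs(trace.fs - 2500.0) > 1e-9 and trace.fs > 3000.0:
        raise ValueError(
            "trace must be resampled to the analysis grid before decoding "
            f"(got fs={trace.fs})"
        )
    n_samples = int(round(trains.duration_ms * trace.fs / 1000.0))
    if len(trace.samples) < n_samples:
        raise ValueError("stimulus shorter than the trial duration")
    fold_of_trial = np.zeros(trains.n_trials, dtype=np.intp)
    filters = []
    parts = np.array_split(np.arange(trains.n_trials), n_folds)
    for f, test_idx in enumerate(parts):
        fold_of_trial[test_idx] = f
        train_idx = np.setdiff1d(np.arange(trains.n_trials), test_idx)
        filters.append(
            fit_filter(trace, _subset(trains, train_idx), kind, causal, window, var_fraction)
        )
    full = fit_filter(trace, trains, kind, causal, window, var_fraction)
    if kind == "pwsta":
        gauge, _ = whiten_signal(trace, var_fraction=var_fraction, window=window)
        gauge_ranks = standardized_ranks(gauge.samples[:n_samples])
    else:
        gauge_ranks = standardized_ranks(trace.samples[:n_samples])
    return FittedDecoder(
        trace=trace, trains=trains, kind=kind, causal=causal, n_folds=n_folds,
        fold_of_trial=fold_of_trial, filters=filters, full_filter=full,
        gauge_ranks=gauge_ranks, n_samples=n_samples,
    )


def crossval_decode(
    trace: StimulusTrace,
    trains: SpikeTrainSet,
    kind: str = "mwiener",
    causal: bool = False,
    n_folds: int = 10,
    n_shuffles: int = 100,
    seed: int = 0,
    window: float = 50.0,
    decoder: FittedDecoder | None = None,
) -> DecodingResult:
    """Cross-validated decoding quality with shuffle-based significance.

    Per test trial i the reconstruction quality is q_i = ρ(z, ẑ_i) (Spearman);
    Q is their mean, and the per-trial empirical p value compares q_i with
    reconstructions of ``n_shuffles`` uniform redraws of that trial's spike
    times: p_i = (1 + #{q_shuffled >= q_i}) / (n_shuffles + 1).  The overall p
    is the geometric mean of the p_i.  With ``n_shuffles=0`` the p values are
    skipped (used internally by the jitter sweeps).
    """
    dec = decoder if decoder is not None else fit_decoder(
        trace, trains, kind, causal, n_folds, window
    )
    q = dec.all_q()
    valid = np.isfinite(q)
    n_excluded = int(np.sum(~valid))
    Q = float(np.mean(q[valid])) if np.any(valid) else np.nan

    p_trials = None
    p_overall = None
    if n_shuffles > 0:
        rng = derive_rng(seed, 11)
        p_trials = np.full(trains.n_trials, np.nan)
        for i, t in enumerate(dec.trains.trials):
            if not valid[i]:
                continue
            exceed = 0
            for _ in range(n_shuffles):
                ts = np.sort(rng.uniform(0.0, trains.duration_ms, size=len(t)))
                if dec.trial_q(i, ts) >= q[i]:
                    exceed += 1
            p_trials[i] = (1.0 + exceed) / (n_shuffles + 1.0)
        p_overall = float(np.exp(np.nanmean(np.log(p_trials))))

    peak = dec.full_filter.peak_lag_ms()
    return DecodingResult(
        unit_id=trains.unit_id, kind=dec.kind, causal=dec.causal,
        q_trials=q, Q=Q, p_trials=p_trials, p_overall=p_overall,
        time_lag_ms=-peak, filter=dec.full_filter, n_folds=dec.n_folds,
        n_excluded=n_excluded,
    )
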