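"""Monosynaptic connectivity from cross-correlation histograms.

For a putative pre/postsynaptic pair, the count CCH (0.4 ms bins, ±50 ms)
is built from spike times in stimulus-free epochs.  The *spike transmission
curve* — the impulse response of spike transmission — is the difference
between the CCH deconvolved by the presynaptic autocorrelation and an
identically deconvolved median-filtered baseline, scaled to spikes/s.  Its
area over the causal peak (region of interest 0 < t <= 5 ms, extended to
the zero crossings) is the *spike transmission gain*: the expected number
of excess postsynaptic spikes per presynaptic spike.  Detection uses a
Bonferroni-corrected Poisson test of the ROI counts against the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import median_filter

from ._core import toeplitz_solve

__all__ = [
    "CCHRecord",
    "TransmissionCurve",
    "compute_cch",
    "compute_ach",
    "transmission_curve",
    "test_monosynaptic",
    "connection_probability",
    "DEFAULT_BIN_MS",
    "ROI_MS",
]

DEFAULT_BIN_MS = 0.4
HALF_RANGE_MS = 50.0
#: monosynaptic region of interest: 13 whole 0.4 ms bins covering (0, 5.2] ms
ROI_MS = (0.0, 5.2)
BASELINE_WINDOW_BINS = 25  # 10 ms centered median filter


class InsufficientDataError(ValueError):
    pass


@dataclass
class CCHRecord:
    """Count cross-correlation histogram of a directed unit pair."""

    pre_id: str
    post_id: str
    bin_ms: float
    lags_ms: np.ndarray  # bin centers, symmetric about 0, odd length
    counts: np.ndarray  # integer counts per bin
    n_pre_spikes: int
    baseline: np.ndarray | None = None  # median-filtered counts

    def with_baseline(self, window_bins: int = BASELINE_WINDOW_BINS) -> "CCHRecord":
        """Attach the centered median-filter baseline (reflected edges)."""
        base = median_filter(self.counts.astype(np.float64), size=window_bins, mode="reflect")
        self.baseline = base
        return self


@dataclass
class TransmissionCurve:
    """Deconvolved, baseline-subtracted CCH in spikes/s, with its gain."""

    pre_id: str
    post_id: str
    lags_ms: np.ndarray
    excess_rate: np.ndarray  # spikes/s
    gain: float  # expected excess postsynaptic spikes per presynaptic spike
    peak_lag_ms: float
    support_ms: tuple[float, float]
    significant: bool
    p_value: float


def _lag_edges(bin_ms: float, half_range_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Centered, half-open bins [left, right) spanning ±half_range, odd count."""
    n_half = int(round(half_range_ms / bin_ms))
    centers = np.arange(-n_half, n_half + 1) * bin_ms
    edges = (np.arange(-n_half, n_half + 2) - 0.5) * bin_ms
    return centers, edges


def compute_cch(
    pre: np.ndarray,
    post: np.ndarray,
    bin_ms: float = DEFAULT_BIN_MS,
    half_range_ms: float = HALF_RANGE_MS,
    pre_id: str = "pre",
    post_id: str = "post",
) -> CCHRecord:
    """Count CCH: counts[k] = #{(i, j) : post_j - pre_i in bin k}.

    Spike times in ms on a common absolute clock (concatenate epochs with
    offsets before calling).  Exact integer counts via sorted search.
    """
    pre = np.sort(np.asarray(pre, dtype=np.float64))
    post = np.sort(np.asarray(post, dtype=np.float64))
    if len(pre) == 0:
        raise InsufficientDataError("empty presynaptic train")
    centers, edges = _lag_edges(bin_ms, half_range_ms)
    # cumulative post counts below each (pre + edge)
    idx = np.searchsorted(post, pre[:, None] + edges[None, :], side="left")
    counts = np.diff(idx, axis=1).sum(axis=0)
    return CCHRecord(
        pre_id=pre_id, post_id=post_id, bin_ms=bin_ms, lags_ms=centers,
        counts=counts.astype(np.int64), n_pre_spikes=len(pre),
    )


def compute_ach(
    train: np.ndarray, bin_ms: float = DEFAULT_BIN_MS, half_range_ms: float = 2 * HALF_RANGE_MS
) -> np.ndarray:
    """Per-spike-normalized autocorrelation histogram on the CCH lag grid,
    zero-lag bin carrying the unit self-coincidence (same convention as the
    decoding module's deconvolution operator).

    The default range is twice the CCH half-range because the Toeplitz
    deconvolution operator of a ±50 ms CCH needs lags out to ±100 ms."""
    t = np.sort(np.asarray(train, dtype=np.float64))
    if len(t) == 0:
        raise InsufficientDataError("empty train")
    rec = compute_cch(t, t, bin_ms, half_range_ms)
    counts = rec.counts.astype(np.float64)
    half = (len(counts) - 1) // 2
    counts[half] -= len(t)  # remove self pairs
    ach = counts / len(t)
    ach[half] += 1.0
    return ach


def transmission_curve(
    cch: CCHRecord,
    pre_ach: np.ndarray,
    alpha: float = 0.001,
    eig_floor: float = 1e-6,
) -> TransmissionCurve:
    """Spike transmission curve and gain of one pair.

    Both the count CCH and its median-filtered baseline are deconvolved by
    the presynaptic ACH (regularized Toeplitz solve); their difference,
    divided by the presynaptic spike count and the bin width in seconds, is
    the excess postsynaptic rate.  The gain is the trapezoidal integral of
    the excess rate over the peak's support: the causal zero crossings
    bracketing the ROI peak.
    """
    if cch.baseline is None:
        cch = cch.with_baseline()
    n = len(cch.counts)
    if len(pre_ach) != 2 * n - 1:
        raise ValueError(
            "pre ACH must span twice the CCH lag range "
            f"(expected {2 * n - 1} bins, got {len(pre_ach)})"
        )
    mid = (len(pre_ach) - 1) // 2
    first_col = np.asarray(pre_ach, dtype=np.float64)[mid : mid + n]
    half = (n - 1) // 2  # index of the zero-lag bin
    dec_cch = toeplitz_solve(first_col, cch.counts.astype(np.float64), eig_floor)
    dec_base = toeplitz_solve(first_col, cch.baseline, eig_floor)
    excess = (dec_cch - dec_base) / (cch.n_pre_spikes * cch.bin_ms * 1e-3)

    significant, p = test_monosynaptic(cch, alpha=alpha)

    roi = (cch.lags_ms > ROI_MS[0] + 1e-9) & (cch.lags_ms <= ROI_MS[1] + 1e-9)
    roi_idx = np.nonzero(roi)[0]
    k_peak = roi_idx[int(np.argmax(excess[roi_idx]))]
    # extend to the zero crossings of the excess rate around the peak
    left = k_peak
    while left - 1 > half and excess[left - 1] > 0:
        left -= 1
    right = k_peak
    while right + 1 < len(excess) and excess[right + 1] > 0:
        right += 1
    seg = slice(left, right + 1)
    gain = float(np.trapezoid(excess[seg], cch.lags_ms[seg] * 1e-3)) if right > left else float(
        excess[k_peak] * cch.bin_ms * 1e-3
    )
    return TransmissionCurve(
        pre_id=cch.pre_id, post_id=cch.post_id, lags_ms=cch.lags_ms,
        excess_rate=excess, gain=gain, peak_lag_ms=float(cch.lags_ms[k_peak]),
        support_ms=(float(cch.lags_ms[left]), float(cch.lags_ms[right])),
        significant=significant, p_value=p,
    )


def test_monosynaptic(cch: CCHRecord, alpha: float = 0.001) -> tuple[bool, float]:
    """Bonferroni-corrected Poisson test of the ROI count CCH bins against
    the median-filter baseline.

    Per ROI bin, the upper-tail Poisson probability of the observed count
    given the baseline expectation; the Bonferroni factor is the number of
    ROI bins (13).  Returns (significant at ``alpha``, min corrected p).
    """
    if cch.baseline is None:
        cch = cch.with_baseline()
    roi = (cch.lags_ms > ROI_MS[0] + 1e-9) & (cch.lags_ms <= ROI_MS[1] + 1e-9)
    lam = cch.baseline[roi]
    obs = cch.counts[roi]
    if np.all(lam == 0):
        raise InsufficientDataError("zero baseline everywhere in the ROI")
    p_bins = stats.poisson.sf(obs - 1, np.maximum(lam, 1e-300))
    p_min = float(np.min(np.minimum(p_bins * roi.sum(), 1.0)))
    return bool(p_min < alpha), p_min


def connection_probability(
    int_id: str,
    unit_table,
    presyn_ids: set[str] | list[str],
    max_dist_um: float = 600.0,
    shank_spacing_um: float = 200.0,
) -> float | None:
    """Fraction of simultaneously recorded pyramidal cells within range that
    are presynaptic to the given interneuron.

    ``unit_table`` is a DataFrame with columns ``unit_id``, ``cell_type``
    ("pyr"/"int"), ``shank`` (integer), ``depth_um``.  Distance is Euclidean
    over (shank separation x ``shank_spacing_um``, depth difference).
    Returns None when no pyramidal cell lies within range.
    """
    row = unit_table.loc[unit_table["unit_id"] == int_id]
    if row.empty:
        raise KeyError(f"unit {int_id!r} not in the table")
    x0 = float(row["shank"].iloc[0]) * shank_spacing_um
    y0 = float(row["depth_um"].iloc[0])
    pyr = unit_table[(unit_table["cell_type"] == "pyr") & (unit_table["unit_id"] != int_id)]
    dx = pyr["shank"].to_numpy(dtype=float) * shank_spacing_um - x0
    dy = pyr["depth_um"].to_numpy(dtype=float) - y0
    in_range = np.hypot(dx, dy) <= max_dist_um
    n_total = int(in_range.sum())
    if n_total == 0:
        return None
    presyn = pyr["unit_id"].isin(set(presyn_ids)).to_numpy()
    return float(np.sum(presyn & in_range) / n_total)
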