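"""Filter models and cross-validated decoding."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.linalg import toeplitz

from wnspike._core import spearman, standardized_ranks
from wnspike.reconstruct import (
    FittedDecoder, InsufficientDataError, compute_sta, conditional_filter_bank,
    crossval_decode, fit_decoder, fit_filter, make_causal, modified_wiener,
    spike_train_ach, whiten_signal,
)
from wnspike.signal import StimulusTrace
from wnspike.simulate import SpikeTrainSet

FS = 2500.0


def _trains(trials, duration_ms=1000.0, unit_id="u"):
    return SpikeTrainSet(unit_id=unit_id, trials=trials, duration_ms=duration_ms)


def _trace(samples):
    z = (samples - samples.mean()) / samples.std()
    return StimulusTrace(samples=z, fs=FS, tau=3.0, seed=0, standardized=True)


class TestSTA:
    def test_single_spike_equals_segment(self, trace_z):
        t0 = 500.0
        sta = compute_sta(trace_z, _trains([np.array([t0])]))
        i = int(round(t0 * FS / 1000.0))
        seg = trace_z.samples[i - 125 : i + 126]
        assert np.allclose(sta.coefficients, seg)

    def test_coefficient_count(self, trace_z, unit_locked):
        sta = compute_sta(trace_z, unit_locked, window=50.0)
        assert len(sta.coefficients) == 251
        assert sta.lags_ms[0] == -50.0 and sta.lags_ms[-1] == 50.0

    def test_sine_maxima_give_centered_sine(self):
        """Spikes at the maxima of a standardized sinusoid produce a windowed
        sinusoid filter peaking at lag 0 with amplitude ~sqrt(2).  The
        frequency is chosen so the window edges are not at a peak."""
        f = 37.0
        t = np.arange(0, 2.0, 1.0 / FS)
        trace = _trace(np.sin(2 * np.pi * f * t))
        peaks = (np.arange(2, int(2.0 * f) - 2) + 0.25) / f
        sta = compute_sta(trace, _trains([peaks * 1000.0], duration_ms=2000.0))
        assert abs(sta.lags_ms[int(np.argmax(sta.coefficients))]) <= 0.4
        assert np.max(sta.coefficients) == pytest.approx(np.sqrt(2.0), rel=5e-3)

    def test_no_spikes_rejected(self, trace_z):
        with pytest.raises(InsufficientDataError):
            compute_sta(trace_z, _trains([np.empty(0)]))


class TestMakeCausal:
    def test_zeroes_positive_lags_idempotently(self, trace_z, unit_locked):
        sta = compute_sta(trace_z, unit_locked)
        c = make_causal(sta)
        assert np.all(c.coefficients[c.lags_ms > 0] == 0)
        assert np.array_equal(c.coefficients[c.lags_ms <= 0],
                              sta.coefficients[sta.lags_ms <= 0])
        assert np.array_equal(make_causal(c).coefficients, c.coefficients)

    def test_symmetric_filter_loses_half_energy(self, trace_z, unit_locked):
        sta = compute_sta(trace_z, unit_locked)
        sym = replace(sta, coefficients=np.abs(sta.coefficients[::-1] + sta.coefficients) / 2)
        c = make_causal(sym)
        e_full = np.sum(sym.coefficients**2)
        e_causal = np.sum(c.coefficients**2)
        # exactly half the off-zero energy survives for a symmetric filter
        assert e_causal == pytest.approx((e_full + sym.coefficients[125] ** 2) / 2)


class TestConditionalBank:
    def test_ten_rows(self, trace_z, unit_locked):
        bank = conditional_filter_bank(trace_z, unit_locked)
        assert bank.coefficients.shape == (10, 251)
        assert len(bank.isi_bin_edges) == 11

    def test_two_cluster_isis_match_restricted_sta(self, trace_z):
        """With ISIs from two separated clusters, the bank rows covering one
        cluster average (spike-weighted) to the cluster-restricted STA."""
        rng = np.random.default_rng(5)
        trials = []
        for _ in range(5):
            t, cur, short = [], 60.0, True
            while cur < 940.0:
                t.append(cur)
                cur += rng.uniform(4, 6) if short else rng.uniform(80, 120)
                short = not short
            trials.append(np.array(t))
        trains = _trains(trials)
        bank = conditional_filter_bank(trace_z, trains)
        from wnspike.reconstruct import _isi_bin_of, _isi_tags, _segments, _spike_indices
        isis, _ = _isi_tags(trains)
        idx = np.concatenate(_spike_indices(trains.trials, FS, len(trace_z.samples)))
        bins = _isi_bin_of(isis, bank.isi_bin_edges)
        # deciles populated exclusively by the short-ISI cluster
        short_bins = [b for b in range(10)
                      if np.any(bins == b) and np.all(isis[bins == b] <= 10.0)]
        assert short_bins, "quantile edges must isolate the short cluster"
        in_short = np.isin(bins, short_bins)
        oracle = _segments(trace_z.samples, idx[in_short], 125).mean(axis=0)
        weights = [np.sum(bins == b) for b in short_bins]
        combined = np.average(bank.coefficients[short_bins], axis=0, weights=weights)
        assert np.allclose(combined, oracle, atol=1e-10)

    def test_tied_isis_rejected(self, trace_z):
        trials = [np.arange(100.0, 900.0, 10.0) for _ in range(3)]
        with pytest.raises(InsufficientDataError):
            conditional_filter_bank(trace_z, _trains(trials))


class TestWhiten:
    def test_white_input_passthrough(self):
        rng = np.random.default_rng(0)
        trace = _trace(rng.standard_normal(5000))
        y, _ = whiten_signal(trace, var_fraction=0.9)
        assert spearman(y.samples[200:-200], trace.samples[200:-200]) > 0.95

    def test_full_rank_operator_is_exact_inverse_sqrt(self, trace_z):
        """At var_fraction=1 the whitening operator satisfies W C W = I."""
        _, W = whiten_signal(trace_z, var_fraction=1.0, window=20.0)
        dim = W.shape[0]
        z = trace_z.samples - trace_z.samples.mean()
        n = len(z)
        acov = np.array([z[: n - k] @ z[k:] / n for k in range(dim)])
        C = toeplitz(acov)
        assert np.allclose(W @ C @ W, np.eye(dim), atol=1e-6)

    def test_colored_input_decorrelated_on_retained_subspace(self, trace_z):
        y, W = whiten_signal(trace_z, var_fraction=0.9)
        s = y.samples - y.samples.mean()
        n = len(s)
        acov = np.array([s[: n - k] @ s[k:] / n for k in range(251)])
        Cy = toeplitz(acov)
        w_eig, V = np.linalg.eigh(Cy)
        # project onto the retained directions of the whitener
        proj = V.T @ Cy @ V
        off = proj - np.diag(np.diag(proj))
        assert np.max(np.abs(off)) < 0.1 * np.max(np.diag(proj))


class TestModifiedWiener:
    def test_sparse_poisson_train_gives_sta_like_filter(self, trace_z):
        """With a flat, sparse ACH the deconvolution operator is close to the
        identity and w stays proportional to the STA.  (At high rates the
        flat ACH legitimately attenuates the filter's low frequencies, so
        the near-identity regime is the sparse one.)"""
        rng = np.random.default_rng(31)
        trials = [np.sort(rng.uniform(0, 999.0, size=2)) for _ in range(25)]
        trains = _trains(trials)
        sta = compute_sta(trace_z, trains)
        w = modified_wiener(sta, trains)
        cos = (sta.coefficients @ w.coefficients) / (
            np.linalg.norm(sta.coefficients) * np.linalg.norm(w.coefficients))
        assert cos > 0.99

    def test_forward_model_reproduces_sta(self, trace_z, unit_locked):
        """A w recovers s on the non-floored eigenspace (relative residual
        below 1e-6)."""
        sta = compute_sta(trace_z, unit_locked)
        w = modified_wiener(sta, unit_locked)
        ach = spike_train_ach(unit_locked, FS, window=100.0)
        mid = (len(ach) - 1) // 2
        A = toeplitz(ach[mid : mid + 251])
        lam, V = np.linalg.eigh(A)
        keep = lam >= 1e-6 * lam.max()
        resid = V.T @ (A @ w.coefficients - sta.coefficients)
        assert np.linalg.norm(resid[keep]) < 1e-6 * np.linalg.norm(sta.coefficients)

    def test_bursty_train_differs_from_sta(self, trace_z):
        rng = np.random.default_rng(8)
        trials = []
        for _ in range(10):
            base = np.sort(rng.uniform(60, 940, size=25))
            burst = np.concatenate([base, base + 5.0])
            trials.append(np.unique(np.sort(burst)))
        trains = _trains(trials)
        sta = compute_sta(trace_z, trains)
        w = modified_wiener(sta, trains)
        cos = (sta.coefficients @ w.coefficients) / (
            np.linalg.norm(sta.coefficients) * np.linalg.norm(w.coefficients))
        assert cos < 0.99  # the 5 ms ACH side lobe reshapes the filter


class TestCrossvalDecode:
    def test_fold_partition(self, trace_z):
        rng = np.random.default_rng(4)
        trains = _trains([np.sort(rng.uniform(0, 999.0, 40)) for _ in range(20)])
        dec = fit_decoder(trace_z, trains, "sta", n_folds=10)
        counts = np.bincount(dec.fold_of_trial, minlength=10)
        assert np.all(counts == 2)
        assert len(dec.filters) == 10

    def test_locked_unit_decodes_significantly(self, trace_z, unit_locked):
        res = crossval_decode(trace_z, unit_locked, kind="mwiener",
                              n_shuffles=40, seed=2)
        assert res.Q > 0.5
        assert res.p_overall < 0.05
        assert abs(res.time_lag_ms) < 5.0  # the sine drive kernel is nearly lag-free
        assert res.Q == pytest.approx(np.nanmean(res.q_trials))
        valid = np.isfinite(res.p_trials)
        assert res.p_overall == pytest.approx(
            np.exp(np.mean(np.log(res.p_trials[valid]))))

    def test_deterministic_delay_sets_time_lag(self, trace_z):
        """Spikes placed a fixed 8 ms after signal peaks give Q > 0.5 and a
        positive reported time lag near the delay (signal precedes spike)."""
        z = trace_z.samples
        d = 8.0
        peaks = [i for i in range(30, 2400)
                 if z[i] > 1.2 and z[i] >= z[i - 1] and z[i] >= z[i + 1]]
        times = np.array(peaks) / FS * 1000.0 + d
        trains = _trains([times.copy() for _ in range(10)])
        res = crossval_decode(trace_z, trains, kind="sta", n_folds=5, n_shuffles=40,
                              seed=4)
        assert res.Q > 0.5
        assert res.p_overall < 0.05
        assert res.time_lag_ms == pytest.approx(d, abs=1.5)

    def test_unstructured_trains_give_null_q(self, trace_z):
        """Trains with no reproducible structure (independent uniform spikes
        per trial) decode at chance with a non-significant shuffle p."""
        rng = np.random.default_rng(99)
        trials = [np.sort(rng.uniform(0, 999.0, size=30)) for _ in range(20)]
        res = crossval_decode(trace_z, _trains(trials), kind="sta",
                              n_shuffles=40, seed=3)
        assert abs(res.Q) < 0.1
        assert res.p_overall > 0.05

    def test_rank_invariance_of_q(self, trace_z, unit_locked):
        """Q is invariant under strictly monotone transforms of the
        reconstruction (rank correlation contract)."""
        dec = fit_decoder(trace_z, unit_locked, "sta")
        from wnspike.reconstruct import reconstruct_trial
        i = 3
        filt = dec.filters[dec.fold_of_trial[i]]
        zhat = reconstruct_trial(filt, unit_locked.trials[i], dec.n_samples)
        q1 = float(standardized_ranks(zhat) @ dec.gauge_ranks)
        q2 = float(standardized_ranks(np.exp(2.0 * zhat)) @ dec.gauge_ranks)
        assert q1 == pytest.approx(q2, abs=1e-12)

    def test_empty_trial_excluded(self, trace_z):
        rng = np.random.default_rng(6)
        trials = [np.sort(rng.uniform(0, 999.0, 30)) for _ in range(9)] + [np.empty(0)]
        res = crossval_decode(trace_z, _trains(trials), kind="sta", n_folds=5,
                              n_shuffles=0)
        assert res.n_excluded == 1
        assert np.isnan(res.q_trials[-1])

    @pytest.mark.parametrize("kind,causal", [
        ("sta", False), ("sta", True), ("csta", False), ("csta", True),
        ("wiener", False), ("wiener", True), ("cwiener", False), ("cwiener", True),
        ("mwiener", False), ("mwiener", True), ("cmwiener", False), ("cmwiener", True),
        ("pwsta", False),
    ])
    def test_all_model_kinds_decode_locked_unit(self, trace_z, unit_locked, kind, causal):
        """Every filter model decodes a signal-locked unit above chance."""
        res = crossval_decode(trace_z, unit_locked, kind=kind, causal=causal,
                              n_shuffles=0)
        assert res.Q > 0.2
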