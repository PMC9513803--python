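"""Cross-correlograms, transmission curves, and monosynaptic detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wnspike.connectivity import (
    InsufficientDataError, compute_ach, compute_cch, connection_probability,
    transmission_curve,
)
from wnspike.connectivity import test_monosynaptic as monosynaptic_test
from wnspike.validation import inject_connected_pair, _poisson_times
from wnspike._core import derive_rng


def _enum_cch(pre, post, bin_ms=0.4, half=50.0):
    n_half = int(round(half / bin_ms))
    counts = np.zeros(2 * n_half + 1, dtype=int)
    for a in pre:
        for b in post:
            k = int(np.floor((b - a) / bin_ms + 0.5))
            if -n_half <= k <= n_half:
                counts[k + n_half] += 1
    return counts


class TestComputeCCH:
    def test_shifted_copy_concentrates_in_one_bin(self):
        # spacing beyond the +-50 ms range, so only the shift lag is counted
        pre = np.arange(100.0, 20000.0, 150.0)
        rec = compute_cch(pre, pre + 1.6)
        k = np.argmax(rec.counts)
        assert rec.lags_ms[k] == pytest.approx(1.6)
        assert rec.counts[k] == len(pre)
        assert rec.counts.sum() == len(pre)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pre = np.sort(rng.uniform(0, 500.0, size=rng.integers(1, 25)))
        post = np.sort(rng.uniform(0, 500.0, size=rng.integers(0, 25)))
        rec = compute_cch(pre, post)
        assert np.array_equal(rec.counts, _enum_cch(pre, post))

    def test_time_reversal_identity(self, rng):
        pre = np.sort(rng.uniform(0, 2000.0, size=120))
        post = np.sort(rng.uniform(0, 2000.0, size=90))
        a = compute_cch(pre, post).counts
        b = compute_cch(post, pre).counts
        assert np.array_equal(a, b[::-1])

    def test_flat_expectation_for_independent_pairs(self, rng):
        la, lb, T = 20.0, 20.0, 100.0
        pre = np.sort(rng.uniform(0, T * 1e3, size=int(la * T)))
        post = np.sort(rng.uniform(0, T * 1e3, size=int(lb * T)))
        rec = compute_cch(pre, post)
        expect = la * lb * T * 0.4e-3
        assert np.all(np.abs(rec.counts - expect) < 4 * np.sqrt(expect) + 1)

    def test_empty_pre_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_cch(np.empty(0), np.array([1.0]))


@pytest.fixture(scope="module")
def injected():
    pre, post = inject_connected_pair(0.2, seed=77)
    ach = compute_ach(pre)
    cch = compute_cch(pre, post).with_baseline()
    return transmission_curve(cch, ach)


class TestTransmissionCurve:

    def test_recovers_injected_gain_and_lag(self, injected):
        assert 0.15 <= injected.gain <= 0.25
        assert 1.2 <= injected.peak_lag_ms <= 2.0
        assert injected.significant

    def test_gain_is_area_over_support(self, injected):
        lo, hi = injected.support_ms
        seg = (injected.lags_ms >= lo) & (injected.lags_ms <= hi)
        area = np.trapezoid(injected.excess_rate[seg], injected.lags_ms[seg] * 1e-3)
        assert injected.gain == pytest.approx(area, abs=1e-9)

    def test_null_pair_gain_negligible(self):
        rng = derive_rng(123, 52)
        pre = _poisson_times(10.0, 600.0, rng)
        post = _poisson_times(10.0, 600.0, rng)
        cch = compute_cch(pre, post).with_baseline()
        curve = transmission_curve(cch, compute_ach(pre))
        assert abs(curve.gain) < 0.01
        assert not curve.significant

    def test_mismatched_ach_grid_rejected(self, injected):
        pre, post = inject_connected_pair(0.1, seed=5)
        cch = compute_cch(pre, post)
        with pytest.raises(ValueError):
            transmission_curve(cch, np.ones(251))


class TestMonosynapticTest:
    def test_counts_equal_baseline_not_significant(self):
        from wnspike.connectivity import CCHRecord
        lags = (np.arange(-125, 126)) * 0.4
        counts = np.full(251, 40, dtype=np.int64)
        rec = CCHRecord(pre_id="a", post_id="b", bin_ms=0.4, lags_ms=lags,
                        counts=counts, n_pre_spikes=1000).with_baseline()
        sig, p = monosynaptic_test(rec)
        assert not sig
        assert p > 0.4  # survival at the observed count is near the median

    def test_detects_injected_connection(self):
        pre, post = inject_connected_pair(0.1, seed=9)
        cch = compute_cch(pre, post).with_baseline()
        sig, p = monosynaptic_test(cch)
        assert sig and p < 1e-3


class TestConnectionProbability:
    @pytest.fixture()
    def table(self):
        rows = [("i0", "int", 0, 0.0)]
        rows += [(f"p{k}", "pyr", k % 4, 50.0 * k) for k in range(20)]
        return pd.DataFrame(rows, columns=["unit_id", "cell_type", "shank", "depth_um"])

    def test_fraction_arithmetic(self, table):
        # exactly the pyramidal cells within 600 um, 3 of them presynaptic
        d = np.hypot(table.shank[1:] * 200.0, table.depth_um[1:])
        in_range = table.unit_id[1:][d <= 600.0].tolist()
        presyn = in_range[:3]
        frac = connection_probability("i0", table, presyn)
        assert frac == pytest.approx(3 / len(in_range))

    def test_matches_bruteforce_scan(self, rng):
        n = 30
        df = pd.DataFrame({
            "unit_id": [f"u{k}" for k in range(n)],
            "cell_type": ["int"] + ["pyr"] * (n - 1),
            "shank": rng.integers(0, 6, size=n),
            "depth_um": rng.uniform(0, 800.0, size=n),
        })
        presyn = {f"u{k}" for k in range(1, n, 3)}
        got = connection_probability("u0", df, presyn)
        x0, y0 = df.shank[0] * 200.0, df.depth_um[0]
        hits = tot = 0
        for _, row in df.iloc[1:].iterrows():
            if np.hypot(row.shank * 200.0 - x0, row.depth_um - y0) <= 600.0:
                tot += 1
                hits += row.unit_id in presyn
        assert got == pytest.approx(hits / tot)

    def test_no_pyr_in_range_is_missing(self):
        df = pd.DataFrame({
            "unit_id": ["i0", "p1"], "cell_type": ["int", "pyr"],
            "shank": [0, 5], "depth_um": [0.0, 0.0],
        })
        assert connection_probability("i0", df, {"p1"}) is None
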