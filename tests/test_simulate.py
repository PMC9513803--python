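"""Point-process simulator: rate profiles, Bernoulli sampling, daughters."""

import numpy as np
import pytest

from wnspike._core import derive_rng
from wnspike.simulate import (
    SimulationConfig, SpikeTrainSet, make_daughter_trains, rate_from_signal,
    sample_poisson_train, simulate_unit, sine_cycle_kernel,
)


class TestRateFromSignal:
    def test_kernel_length(self):
        assert len(sine_cycle_kernel(100.0, 2500.0)) == 25

    def test_zero_signal_gives_zero_rate(self, trace_z):
        from dataclasses import replace
        flat = replace(trace_z, samples=np.zeros_like(trace_z.samples))
        rate = rate_from_signal(flat, 100.0, 25.0)
        assert np.all(rate == 0)

    def test_matches_loop_oracle(self, trace_z):
        """Causal convolution, rectification, and mean scaling agree with an
        explicit per-sample loop."""
        lam = 40.0
        rate = rate_from_signal(trace_z, 100.0, lam)
        k = sine_cycle_kernel(100.0, trace_z.fs)
        z = trace_z.samples
        n = 400  # prefix is enough for an exact check
        oracle = np.zeros(n)
        for t in range(n):
            acc = 0.0
            for j, kv in enumerate(k):
                if t - j >= 0:
                    acc += z[t - j] * kv
            oracle[t] = max(acc, 0.0)
        full = np.maximum(np.convolve(z, k, "full")[: len(z)], 0.0)
        scale = lam / full.mean()
        assert np.allclose(rate[:n], oracle * scale, atol=1e-10)

    def test_mean_equals_lambda1(self, trace_z):
        rate = rate_from_signal(trace_z, 100.0, 33.0)
        assert rate.mean() == pytest.approx(33.0)
        assert np.all(rate >= 0)

    def test_requires_standardized(self, trace_raw):
        with pytest.raises(ValueError):
            rate_from_signal(trace_raw.resample(2500.0), 100.0, 10.0)


class TestSamplePoisson:
    def test_zero_rate_empty(self, rng):
        assert len(sample_poisson_train(np.zeros(1000), 2500.0, 2.0, rng)) == 0

    def test_homogeneous_count_within_binomial_bounds(self, rng):
        lam, T = 20.0, 100.0
        rate = np.full(int(T * 2500), lam)
        t = sample_poisson_train(rate, 2500.0, 0.0, rng)
        assert abs(len(t) - lam * T) < 4 * np.sqrt(lam * T)

    def test_min_isi_enforced(self, rng):
        rate = np.full(25000, 400.0)
        t = sample_poisson_train(rate, 2500.0, 2.0, rng)
        assert len(t) > 100
        assert np.min(np.diff(t)) >= 2.0


class TestDaughters:
    def test_identity_with_no_degradation(self, rng):
        mother = np.array([10.0, 55.0, 400.0, 990.0])
        out = make_daughter_trains(mother, 5, 0.0, 0, 0, 1000.0, rng)
        for d in out:
            assert np.array_equal(d, mother)

    def test_count_bounds(self, rng):
        """Each daughter has between m - r and m + r spikes."""
        mother = np.sort(rng.uniform(0, 1000.0, size=40))
        r = 7
        for d in make_daughter_trains(mother, 200, 1.0, r, r, 1000.0, rng):
            assert 40 - r <= len(d) <= 40 + r

    def test_jitter_magnitude_half_normal(self, rng):
        """Mean |displacement| of matched spikes approximates sd*sqrt(2/pi)."""
        sd = 3.0
        mother = np.arange(50.0, 99950.0, 100.0)  # well separated spikes
        d = make_daughter_trains(mother, 1, sd, 0, 0, 100000.0, rng)[0]
        disp = np.abs(d - mother)
        assert abs(disp.mean() - sd * np.sqrt(2 / np.pi)) < 0.1 * sd

    def test_negative_jitter_rejected(self, rng):
        with pytest.raises(ValueError):
            make_daughter_trains(np.array([1.0]), 1, -1.0, 0, 0, 10.0, rng)


class TestSimulateUnit:
    def test_trial_count_and_bounds(self, trace_z, unit_locked):
        assert unit_locked.n_trials == 25
        for t in unit_locked.trials:
            assert np.all(np.diff(t) > 0)
            assert t[0] >= 0 and t[-1] < unit_locked.duration_ms

    def test_zero_rates_give_empty_trials(self, trace_z):
        cfg = SimulationConfig(lambda1=0.0, lambda2=0.0, sigma1=0.0, sigma2=0.0, seed=3)
        out = simulate_unit(cfg, trace_z)
        assert all(len(t) == 0 for t in out.trials)

    def test_zero_degradation_trials_identical(self, trace_z):
        cfg = SimulationConfig(lambda1=50.0, sigma1=0.0, lambda2=20.0, sigma2=0.0,
                               n_add=0, seed=5)
        out = simulate_unit(cfg, trace_z)
        for t in out.trials[1:]:
            assert np.array_equal(t, out.trials[0])

    def test_mean_count_matches_mothers(self, trace_z):
        """Per-trial counts track the refractory-adjusted mother counts."""
        cfg = SimulationConfig(lambda1=100.0, sigma1=10.0, lambda2=200.0, sigma2=60.0,
                               n_add=0, seed=9)
        out = simulate_unit(cfg, trace_z)
        expected = out.meta["n_mother_signal"] + out.meta["n_mother_noise"]
        counts = [len(t) for t in out.trials]
        assert np.mean(counts) == pytest.approx(expected, rel=0.05)

    def test_seed_determinism(self, trace_z):
        cfg = SimulationConfig(lambda1=80.0, sigma1=4.0, n_add=10, seed=21)
        a = simulate_unit(cfg, trace_z)
        b = simulate_unit(cfg, trace_z)
        assert all(np.array_equal(x, y) for x, y in zip(a.trials, b.trials))

    def test_n_remove_must_match_n_add(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_add=5, n_remove=3)


class TestSpikeTrainSet:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SpikeTrainSet(unit_id="x", trials=[np.array([3.0, 2.0])], duration_ms=10.0)
        with pytest.raises(ValueError):
            SpikeTrainSet(unit_id="x", trials=[np.array([5.0, 12.0])], duration_ms=10.0)

    def test_rate_and_pool(self):
        ts = SpikeTrainSet(unit_id="x", trials=[np.array([1.0, 5.0]), np.array([2.0])],
                           duration_ms=1000.0)
        assert ts.mean_rate() == pytest.approx(1.5)
        assert np.allclose(ts.pooled(), [1.0, 5.0, 1002.0])
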