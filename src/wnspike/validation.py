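"""Validation studies: parameter-recovery and calibration experiments.

These routines re-run the framework's own ground-truth checks end to end:
simulate units with known signal/noise jitter, recover precision and the
reliability timescale, calibrate the connectivity detector on injected
connections and null pairs, reproduce the coincidence-detection
error-correction effect, and verify the algebraic identities of the core
estimators against brute-force oracles.  They are used by the test suite
and by ``scripts/acceptance.py``.

Problem sizes (seeds, repetitions, durations) are the studies' own design;
see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ._core import derive_rng, spearman
from .connectivity import (
    CCHRecord, TransmissionCurve, compute_ach, compute_cch, test_monosynaptic,
    transmission_curve,
)
from .precision import ScreeningError, precision_sweep
from .reconstruct import crossval_decode, fit_decoder
from .reliability import reliability_profile
from .signal import generate_wn_signal, standardize
from .simulate import SimulationConfig, simulate_unit
from .stats import poisson_upper_tail, rank_corr_perm_test
from .transmission import SINTConfig, combine_cd2, combine_ll, combine_sp, generate_sint, presyn_rate

__all__ = [
    "study_precision_recovery",
    "study_reliability_recovery",
    "study_quadrants",
    "study_oracle_identities",
    "study_connectivity_calibration",
    "study_cd_error_correction",
    "study_test_calibration",
    "synthetic_transmission_curve",
]

FS_ANALYSIS = 2500.0
N_SHUFFLES = 40  # shuffle count for AC screening in the studies
N_JITTER_REPS = 5  # jitter realizations per delta in the studies


def _analysis_trace(seed: int):
    """The fixed 1 s stimulus (6 kHz, tau = 3 ms), resampled to the analysis
    grid and standardized."""
    raw = generate_wn_signal(1.0, 6000.0, 3.0, seed)
    return standardize(raw.resample(FS_ANALYSIS))


def _unit_precision(trace_z, cfg, seed_key, kind="mwiener", require_screen=True):
    """Simulate one unit and return its precision P (NaN if it fails the AC
    screen or shows no deterioration).

    Parameter-recovery studies pass ``require_screen=False``: the AC gate
    is a data-quality filter for recorded units, and at large ground-truth
    jitter it rejects nearly every simulated unit, which would leave the
    recovery claim untestable rather than falsifiable.
    """
    trains = simulate_unit(cfg, trace_z, unit_id=f"u{seed_key}")
    dec = fit_decoder(trace_z, trains, kind=kind)
    decoding = None
    if require_screen:
        decoding = crossval_decode(trace_z, trains, kind=kind, n_shuffles=N_SHUFFLES,
                                   seed=cfg.seed, decoder=dec)
    try:
        res = precision_sweep(trace_z, trains, kind=kind, n_jitter_reps=N_JITTER_REPS,
                              seed=cfg.seed, decoding=decoding, decoder=dec,
                              require_screen=require_screen)
    except ScreeningError:
        return np.nan, decoding
    return (res.P_ms if res.detected else np.nan), decoding


# ---------------------------------------------------------------------------
# 1. precision recovery
# ---------------------------------------------------------------------------

def study_precision_recovery(seed: int, n_seeds: int = 20,
                             sigma1_grid=(1.0, 2.0, 4.0, 8.0, 16.0)) -> dict:
    """Recover signal jitter as precision: P vs sigma1 at lambda1 = 100,
    lambda2 = 0.

    Returns the Spearman correlation of the per-sigma1 seed-median P with
    sigma1, and the worst fold error median(P)/sigma1 for sigma1 >= 2 ms.
    """
    trace_z = _analysis_trace(seed)
    sigma1_grid = np.asarray(sigma1_grid, dtype=float)
    P = np.full((len(sigma1_grid), n_seeds), np.nan)
    for i, s1 in enumerate(sigma1_grid):
        for s in range(n_seeds):
            cfg = SimulationConfig(lambda1=100.0, sigma1=float(s1), lambda2=0.0,
                                   sigma2=0.0, n_add=0,
                                   seed=(seed * 1009 + i * 101 + s) % 2**31)
            P[i, s], _ = _unit_precision(trace_z, cfg, seed_key=f"{i}_{s}",
                                         require_screen=False)
    med = np.nanmedian(P, axis=1)
    cc = spearman(sigma1_grid, med)
    big = sigma1_grid >= 2.0
    with np.errstate(invalid="ignore"):
        fold = np.maximum(med[big] / sigma1_grid[big], sigma1_grid[big] / med[big])
    return {
        "sigma1_grid": sigma1_grid,
        "P_medians": med,
        "P_all": P,
        "spearman_medians": float(cc),
        "max_fold_error": float(np.nanmax(fold)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# 2. reliability-timescale recovery
# ---------------------------------------------------------------------------

def study_reliability_recovery(seed: int, n_seeds: int = 20,
                               sigma2_grid=(4.0, 16.0, 64.0),
                               sigma1_grid=(1.0, 2.0, 4.0, 8.0, 16.0)) -> dict:
    """Rp rises with the noise jitter sigma2 and stays flat in the signal
    jitter sigma1.

    The sigma2 sweep fixes sigma1 = 10 ms; the sigma1 sweep fixes the noise
    at lambda2 = 200 spikes/s, sigma2 = 60 ms (the long-timescale regime).
    """
    trace_z = _analysis_trace(seed)
    sigma2_grid = np.asarray(sigma2_grid, dtype=float)
    sigma1_grid = np.asarray(sigma1_grid, dtype=float)

    Rp2 = np.full((len(sigma2_grid), n_seeds), np.nan)
    rise2 = np.full((len(sigma2_grid), n_seeds), np.nan)
    for i, s2 in enumerate(sigma2_grid):
        for s in range(n_seeds):
            cfg = SimulationConfig(lambda1=100.0, sigma1=10.0, lambda2=200.0,
                                   sigma2=float(s2), n_add=25,
                                   seed=(seed * 2027 + i * 211 + s) % 2**31)
            trains = simulate_unit(cfg, trace_z, unit_id=f"r2_{i}_{s}")
            prof = reliability_profile(trains, fs=FS_ANALYSIS)
            Rp2[i, s] = prof.Rp_ms
            # half-rise timescale: smallest coarse sigma reaching half the
            # profile maximum — tracks the noise jitter even when the argmax
            # saturates at the grid ceiling
            rc = prof.r_values[prof.coarse_mask]
            sc = prof.sigmas[prof.coarse_mask]
            above = np.nonzero(rc >= 0.5 * rc.max())[0]
            rise2[i, s] = float(sc[above[0]]) if len(above) else np.nan

    Rp1 = np.full((len(sigma1_grid), n_seeds), np.nan)
    for i, s1 in enumerate(sigma1_grid):
        for s in range(n_seeds):
            cfg = SimulationConfig(lambda1=100.0, sigma1=float(s1), lambda2=200.0,
                                   sigma2=60.0, n_add=25,
                                   seed=(seed * 3041 + i * 223 + s) % 2**31)
            trains = simulate_unit(cfg, trace_z, unit_id=f"r1_{i}_{s}")
            Rp1[i, s] = reliability_profile(trains, fs=FS_ANALYSIS).Rp_ms

    med2 = np.nanmedian(Rp2, axis=1)
    strictly_increasing = bool(np.all(np.diff(med2) > 0))
    rise_med = np.nanmedian(rise2, axis=1)
    x = np.repeat(sigma1_grid, n_seeds)
    y = Rp1.ravel()
    ok = np.isfinite(y)
    if np.all(y[ok] == y[ok][0]):
        trend_cc, trend_p = 0.0, 1.0  # perfectly flat: no trend by construction
    else:
        trend_cc, trend_p = rank_corr_perm_test(x[ok], y[ok], n_perm=999, seed=seed)
    return {
        "sigma2_grid": sigma2_grid, "Rp_medians_vs_sigma2": med2,
        "strictly_increasing": strictly_increasing,
        "nondecreasing": bool(np.all(np.diff(med2) >= 0)),
        "rise_medians_vs_sigma2": rise_med,
        "rise_strictly_increasing": bool(np.all(np.diff(rise_med) > 0)),
        "sigma1_grid": sigma1_grid, "Rp_vs_sigma1": Rp1,
        "sigma1_trend_cc": float(trend_cc), "sigma1_trend_p": float(trend_p),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# 3. precision/reliability quadrants
# ---------------------------------------------------------------------------

#: the four artificial-example parameter sets (lambda1, sigma1, lambda2,
#: sigma2, n_add) spanning the precision x reliability-timescale quadrants
QUADRANT_CONFIGS = {
    "F": dict(lambda1=25.0, sigma1=3.0, lambda2=0.0, sigma2=0.0, n_add=25),
    "G": dict(lambda1=100.0, sigma1=10.0, lambda2=0.0, sigma2=0.0, n_add=0),
    "H": dict(lambda1=100.0, sigma1=1.0, lambda2=0.0, sigma2=0.0, n_add=10),
    "I": dict(lambda1=100.0, sigma1=10.0, lambda2=200.0, sigma2=60.0, n_add=0),
}
QUADRANT_CLASSES = {"F": "temporal", "G": "rate", "H": "temporal", "I": "rate"}


def study_quadrants(seed: int, n_seeds: int = 20) -> dict:
    """The four printed parameter sets dissociate precision from the
    reliability timescale: P(F) > P(H), Rp(G) > Rp(F), Rp(I) > Rp(H), and
    the coder classes are {F, H: temporal; G, I: rate}."""
    trace_z = _analysis_trace(seed)
    checks = {k: 0 for k in ("P_F_gt_H", "Rp_G_gt_F", "Rp_I_gt_H", "classes")}
    per_seed = []
    for s in range(n_seeds):
        res = {}
        for j, (name, pars) in enumerate(QUADRANT_CONFIGS.items()):
            cfg = SimulationConfig(seed=(seed * 4057 + j * 307 + s) % 2**31, **pars)
            trains = simulate_unit(cfg, trace_z, unit_id=f"q{name}_{s}")
            prof = reliability_profile(trains, fs=FS_ANALYSIS)
            entry = {"Rp": prof.Rp_ms, "class": prof.coder_class, "P": np.nan}
            if name in ("F", "H"):
                entry["P"], _ = _unit_precision(trace_z, cfg, seed_key=f"q{name}_{s}",
                                                require_screen=False)
            res[name] = entry
        ok_P = np.isfinite(res["F"]["P"]) and np.isfinite(res["H"]["P"]) \
            and res["F"]["P"] > res["H"]["P"]
        checks["P_F_gt_H"] += ok_P
        checks["Rp_G_gt_F"] += res["G"]["Rp"] > res["F"]["Rp"]
        checks["Rp_I_gt_H"] += res["I"]["Rp"] > res["H"]["Rp"]
        checks["classes"] += all(
            res[k]["class"] == QUADRANT_CLASSES[k] for k in QUADRANT_CLASSES
        )
        per_seed.append(res)
    return {
        "counts": checks,
        "min_count": int(min(checks.values())),
        "n_seeds": n_seeds,
        "per_seed": per_seed,
    }


# ---------------------------------------------------------------------------
# 4. brute-force oracle identities
# ---------------------------------------------------------------------------

def _sta_loop_oracle(z, spike_idx, half):
    """STA by explicit looping over spikes and lags (zero-padded edges)."""
    out = np.zeros(2 * half + 1)
    for i in spike_idx:
        for k, lag in enumerate(range(-half, half + 1)):
            j = i + lag
            if 0 <= j < len(z):
                out[k] += z[j]
    return out / len(spike_idx)


def _cch_enum_oracle(pre, post, bin_ms, half_range_ms):
    """CCH by enumerating every spike pair."""
    n_half = int(round(half_range_ms / bin_ms))
    counts = np.zeros(2 * n_half + 1, dtype=int)
    for a in pre:
        for b in post:
            d = b - a
            k = int(np.floor(d / bin_ms + 0.5))
            if -n_half <= k <= n_half:
                counts[k + n_half] += 1
    return counts


def _cd_sample_oracle(xs, gamma, model):
    """Per-sample evaluation of the CD combination formulas."""
    n_in, n = xs.shape
    y = np.zeros(n)
    for t in range(n):
        act = [xs[i, t] for i in range(n_in) if xs[i, t] > 0]
        m = len(act)
        if m == 0:
            y[t] = 0.0
        elif m == 1:
            y[t] = act[0]
        elif model == "CD1":
            prod = 1.0
            for v in act:
                prod *= v + gamma
            y[t] = prod - gamma**m
        else:
            y[t] = sum(act) * gamma ** (m - 1)
    return y


def study_oracle_identities(seed: int) -> dict:
    """Exact equivalences of the core estimators with brute-force oracles.

    Covers: STA vs an explicit double loop; the modified-Wiener solve
    residual ||A w - s|| / ||s||; the CCH vs full pair enumeration; the CD
    combination rules vs their per-sample formulas; CD2(gamma=1) == SP; and
    single-input CD == LL.  Returns the worst absolute error.
    """
    rng = derive_rng(seed, 91)
    errors = {}

    # STA vs loop oracle
    from .reconstruct import compute_sta, modified_wiener, spike_train_ach
    from .signal import StimulusTrace
    from .simulate import SpikeTrainSet
    z = rng.standard_normal(2000)
    z = (z - z.mean()) / z.std()
    trace = StimulusTrace(samples=z, fs=FS_ANALYSIS, tau=3.0, seed=seed, standardized=True)
    times = np.sort(rng.choice(np.arange(100, 1900), size=60, replace=False)) / FS_ANALYSIS * 1e3
    trains = SpikeTrainSet(unit_id="o", trials=[times], duration_ms=2000 / FS_ANALYSIS * 1e3)
    sta = compute_sta(trace, trains, window=50.0)
    idx = np.round(times * FS_ANALYSIS / 1e3).astype(int)
    oracle = _sta_loop_oracle(z, idx, sta.half_len)
    errors["sta_vs_loop"] = float(np.max(np.abs(sta.coefficients - oracle)))

    # modified Wiener residual on the retained (non-floored) subspace
    from scipy.linalg import toeplitz as _toep
    w_filt = modified_wiener(sta, trains)
    ach = spike_train_ach(trains, FS_ANALYSIS, window=100.0)
    mid = (len(ach) - 1) // 2
    A = _toep(ach[mid : mid + 2 * sta.half_len + 1])
    lam, V = np.linalg.eigh(A)
    keep = lam >= 1e-6 * lam.max()
    resid_vec = V.T @ (A @ w_filt.coefficients - sta.coefficients)
    resid = np.linalg.norm(resid_vec[keep])
    errors["mwiener_residual"] = float(resid / np.linalg.norm(sta.coefficients))

    # CCH vs pair enumeration
    pre = np.sort(rng.uniform(0, 2000.0, size=120))
    post = np.sort(rng.uniform(0, 2000.0, size=150))
    rec = compute_cch(pre, post)
    errors["cch_vs_enum"] = float(
        np.max(np.abs(rec.counts - _cch_enum_oracle(pre, post, rec.bin_ms, 50.0)))
    )

    # CD rules vs per-sample formulas, CD2(1) == SP, single-input CD == LL
    xs = rng.uniform(0, 30, size=(4, 500))
    xs[rng.random(xs.shape) < 0.6] = 0.0
    from .transmission import combine_cd1, combine_cd2
    g = 7.5
    errors["cd1_vs_formula"] = float(np.max(np.abs(combine_cd1(xs, g) - _cd_sample_oracle(xs, g, "CD1"))))
    errors["cd2_vs_formula"] = float(np.max(np.abs(combine_cd2(xs, g) - _cd_sample_oracle(xs, g, "CD2"))))
    errors["cd2_gamma1_vs_sp"] = float(np.max(np.abs(combine_cd2(xs, 1.0) - combine_sp(xs))))
    x1 = xs[:1]
    errors["cd1_single_vs_ll"] = float(np.max(np.abs(combine_cd1(x1, g) - combine_ll(x1))))
    errors["cd2_single_vs_ll"] = float(np.max(np.abs(combine_cd2(x1, g) - combine_ll(x1))))

    errors["max_abs_error"] = float(max(errors.values()))
    return errors


# ---------------------------------------------------------------------------
# 5. connectivity calibration
# ---------------------------------------------------------------------------

def _poisson_times(rate: float, duration_s: float, rng) -> np.ndarray:
    n = rng.poisson(rate * duration_s)
    return np.sort(rng.uniform(0.0, duration_s * 1e3, size=n))


def inject_connected_pair(p: float, seed: int, rate_pre: float = 10.0,
                          rate_post_bg: float = 10.0, duration_s: float = 200.0,
                          lag_ms: float = 1.6, lag_jitter_ms: float = 0.3):
    """Simulate a pre/post pair with a known spike-transmission probability:
    each presynaptic spike elicits a postsynaptic spike with probability
    ``p`` at ``lag_ms`` (Gaussian-jittered), on top of independent background."""
    rng = derive_rng(seed, 51)
    pre = _poisson_times(rate_pre, duration_s, rng)
    bg = _poisson_times(rate_post_bg, duration_s, rng)
    hit = rng.random(len(pre)) < p
    evoked = pre[hit] + rng.normal(lag_ms, lag_jitter_ms, size=int(hit.sum()))
    post = np.sort(np.concatenate([bg, evoked]))
    return pre, post


def study_connectivity_calibration(seed: int, p_grid=(0.05, 0.1, 0.2, 0.4),
                                   n_seeds: int = 20, n_null: int = 1000) -> dict:
    """Gain recovery on injected connections and type-I rate on null pairs.

    Injected pairs use a 1.6 ms transmission lag with 0.3 ms jitter; the
    detector's false-positive rate is measured on independent Poisson pairs
    with session-realistic sizes (pyramidal 2 spikes/s, interneuron 10
    spikes/s, 30 min of stimulus-free recording).
    """
    gains = {p: [] for p in p_grid}
    peaks = {p: [] for p in p_grid}
    for i, p in enumerate(p_grid):
        for s in range(n_seeds):
            pre, post = inject_connected_pair(p, seed=(seed * 5077 + i * 401 + s) % 2**31)
            ach = compute_ach(pre)
            cch = compute_cch(pre, post).with_baseline()
            curve = transmission_curve(cch, ach)
            gains[p].append(curve.gain)
            peaks[p].append(curve.peak_lag_ms)
    med_gain = {p: float(np.median(v)) for p, v in gains.items()}
    med_peak = {p: float(np.median(v)) for p, v in peaks.items()}
    rel_err = {p: abs(med_gain[p] - p) / p for p in p_grid}
    peak_err = {p: abs(med_peak[p] - 1.6) for p in p_grid}

    rng_base = seed * 6089
    fp = 0
    for s in range(n_null):
        rng = derive_rng((rng_base + s) % 2**31, 52)
        pre = _poisson_times(2.0, 1800.0, rng)
        post = _poisson_times(10.0, 1800.0, rng)
        cch = compute_cch(pre, post).with_baseline()
        sig, _ = test_monosynaptic(cch)
        fp += sig
    return {
        "median_gain": med_gain, "median_peak_lag": med_peak,
        "max_gain_rel_error": float(max(rel_err.values())),
        "max_peak_lag_error": float(max(peak_err.values())),
        "false_positive_rate": fp / n_null, "n_null": n_null, "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# 6. coincidence-detection error correction
# ---------------------------------------------------------------------------

def synthetic_transmission_curve(gain: float, peak_ms: float = 1.6,
                                 rise_ms: float = 0.8, fall_ms: float = 3.2,
                                 bin_ms: float = 0.4, half_range_ms: float = 50.0):
    """A synthetic spike-transmission curve (not derived from any recorded
    pair): a single causal alpha-shaped lobe between ``rise_ms`` and
    ``fall_ms`` whose area equals ``gain`` excess spikes per presynaptic
    spike."""
    n_half = int(round(half_range_ms / bin_ms))
    lags = np.arange(-n_half, n_half + 1) * bin_ms
    shape = np.zeros_like(lags)
    sel = (lags > rise_ms - 1e-9) & (lags <= fall_ms + 1e-9)
    t = lags[sel] - rise_ms
    tau = max(peak_ms - rise_ms, bin_ms)
    shape[sel] = t * np.exp(-t / tau)
    area = np.trapezoid(shape, lags * 1e-3)
    shape *= gain / area
    return TransmissionCurve(
        pre_id="syn", post_id="sint", lags_ms=lags, excess_rate=shape,
        gain=float(gain), peak_lag_ms=peak_ms, support_ms=(rise_ms, fall_ms),
        significant=True, p_value=0.0,
    )


def study_cd_error_correction(seed: int, n_seeds: int = 20, n_pyr: int = 8,
                              fr_wn: float = 28.0) -> dict:
    """A pool of converging pyramidal cells driving a nonlinear-summation
    (CD2) target yields error correction (higher Q) and improved precision
    (lower P) relative to the median presynaptic cell, while labeled-line
    and summed-population targets with rate-equalized background mostly
    fail the stimulus-locked (AC) screen.

    The presynaptic pool emulates directly activated pyramidal cells at
    their observed operating point: ~12 spikes/s during stimulation of
    which a third is incoherent background, 3 ms signal jitter, decoding
    quality ~0.13.  Pair gains are drawn uniformly from 0.01-0.03 and the
    target rate is the observed interneuron stimulation rate (28 spikes/s).
    The CD2 nonlinearity is set to twice the median single-synapse peak
    drive, the regime where pairwise coincidences dominate the output.
    Error correction (higher Q) rests on coincidence selection of
    signal-locked spikes plus the higher postsynaptic rate; the precision
    gain is the weaker of the two effects.
    """
    trace_z = _analysis_trace(seed)
    n_samples = int(round(trace_z.duration * FS_ANALYSIS))
    duration_ms = 1000.0

    cd_ok = 0
    cd_ac = 0
    cd_dq = 0
    cd_dp = 0
    ll_fail = 0
    sp_fail = 0
    details = []
    for s in range(n_seeds):
        rng = derive_rng((seed * 7103 + s) % 2**31, 61)
        pyr_trains = []
        xs = []
        qs, ps = [], []
        for k in range(n_pyr):
            cfg = SimulationConfig(lambda1=8.0, sigma1=3.0, lambda2=4.0, sigma2=60.0,
                                   n_add=5, seed=(seed * 7103 + s * 37 + k) % 2**31)
            trains = simulate_unit(cfg, trace_z, unit_id=f"pyr{k}_{s}")
            pyr_trains.append(trains)
            gain = rng.uniform(0.01, 0.03)
            curve = synthetic_transmission_curve(gain)
            xs.append(presyn_rate(trains.trials, curve, FS_ANALYSIS, n_samples))
            P, dec = _unit_precision(trace_z, cfg, seed_key=f"pyr{k}_{s}")
            # reuse the already-simulated trains' decoding for Q
            qs.append(dec.Q)
            ps.append(P)
        xs = np.stack(xs)  # (n_pyr, n_trials, n_samples)
        gamma = 2.0 * float(np.median([x.max() for x in xs]))

        def _build(model):
            if model == "LL":
                y = np.stack([combine_ll(xs[:1, k, :]) for k in range(xs.shape[1])])
            elif model == "SP":
                y = np.stack([combine_sp(xs[:, k, :]) for k in range(xs.shape[1])])
            else:
                y = np.stack([combine_cd2(xs[:, k, :], gamma) for k in range(xs.shape[1])])
            cfg_s = SINTConfig(model=model if model != "CD" else "CD2", fr_wn=fr_wn,
                               gamma=gamma, seed=(seed * 8111 + s) % 2**31)
            return generate_sint(y, FS_ANALYSIS, duration_ms, cfg_s,
                                 unit_id=f"sint_{model}_{s}")

        res_seed = {"gamma": gamma}
        for model in ("LL", "SP", "CD2"):
            sint = _build(model)
            dec = fit_decoder(trace_z, sint, kind="mwiener")
            # 200 shuffles: the geometric-mean p saturates at the per-trial
            # floor 1/(n+1), and borderline targets need the finer resolution
            decoding = crossval_decode(trace_z, sint, kind="mwiener",
                                       n_shuffles=200,
                                       seed=(seed * 9127 + s) % 2**31, decoder=dec)
            passed_ac = decoding.p_overall is not None and decoding.p_overall < 0.05
            res_seed[f"{model}_ac_pass"] = passed_ac
            res_seed[f"{model}_Q"] = decoding.Q
            if model == "CD2":
                if passed_ac:
                    sweep = precision_sweep(trace_z, sint, kind="mwiener",
                                            n_jitter_reps=N_JITTER_REPS,
                                            seed=(seed * 9127 + s) % 2**31,
                                            decoding=decoding, decoder=dec)
                    P_cd = sweep.P_ms if sweep.detected else np.nan
                else:
                    P_cd = np.nan
                res_seed["CD2_P"] = P_cd
        qs_ok = [q for q in qs if q is not None and np.isfinite(q)]
        ps_ok = [p for p in ps if np.isfinite(p)]
        med_q = float(np.median(qs_ok)) if qs_ok else np.nan
        med_p = float(np.median(ps_ok)) if ps_ok else np.nan
        res_seed["pyr_Q_median"] = med_q
        res_seed["pyr_P_median"] = med_p
        dq = res_seed["CD2_Q"] - med_q
        dp = med_p - res_seed["CD2_P"] if np.isfinite(res_seed["CD2_P"]) else -np.inf
        cd_ac += res_seed["CD2_ac_pass"]
        cd_dq += res_seed["CD2_ac_pass"] and dq > 0
        cd_dp += res_seed["CD2_ac_pass"] and dp > 0
        cd_ok += res_seed["CD2_ac_pass"] and dq > 0 and dp > 0
        ll_fail += not res_seed["LL_ac_pass"]
        sp_fail += not res_seed["SP_ac_pass"]
        details.append(res_seed)
    return {
        "cd_success_count": int(cd_ok), "cd_ac_count": int(cd_ac),
        "cd_error_correction_count": int(cd_dq), "cd_precision_count": int(cd_dp),
        "ll_fail_count": int(ll_fail), "sp_fail_count": int(sp_fail),
        "n_seeds": n_seeds, "per_seed": details,
    }


# ---------------------------------------------------------------------------
# 7. test-statistic calibration
# ---------------------------------------------------------------------------

def study_test_calibration(seed: int, n_sim: int = 2000, n: int = 50,
                           n_perm: int = 99, dc_expectation: float = 400.0) -> dict:
    """Empirical type-I error at nominal alpha = 0.05 of the rank-correlation
    permutation test (independent Gaussians, n = 50) and the upper-tail
    Poisson DC test (null counts at expectation 400, e.g. 8 spikes/s
    baseline over 50 s of stimulation)."""
    rng = derive_rng(seed, 71)
    rej_perm = 0
    for _ in range(n_sim):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        _, p = rank_corr_perm_test(x, y, n_perm=n_perm,
                                   seed=int(rng.integers(0, 2**31)))
        rej_perm += p <= 0.05
    rej_pois = 0
    for _ in range(n_sim):
        count = rng.poisson(dc_expectation)
        p = poisson_upper_tail(int(count), dc_expectation)
        rej_pois += p < 0.05
    return {
        "perm_test_type1": rej_perm / n_sim,
        "poisson_test_type1": rej_pois / n_sim,
        "n_sim": n_sim,
    }
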