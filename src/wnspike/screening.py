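"""Unit-inclusion screening.

A unit enters the timing analyses only if it (1) was tested on at least
five stimulation trials, fired at least two spikes per trial on average,
and shows a *DC response* — a mean stimulation-epoch rate consistently above
the spontaneous baseline rate (upper-tail Poisson test on the pooled count);
(2) shows an *AC response* — consistent cross-validated decoding quality
(shuffle test); and (3) is *reliable* — trial-pair reliability consistently
above zero.  Gates are applied sequentially and the first failing stage is
recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

from .reconstruct import DecodingResult
from .reliability import ReliabilityProfile
from .simulate import SpikeTrainSet
from .stats import poisson_upper_tail

__all__ = ["ScreeningReport", "dc_gain_test", "screen_unit"]


@dataclass
class ScreeningReport:
    unit_id: str
    n_trials: int
    mean_spikes_per_trial: float
    dc_gain: float | None
    dc_p: float | None
    ac_p: float | None
    rel_p: float | None
    passed: bool
    failure_stage: str  # {"trials", "dc", "ac", "reliability", "none"}


def dc_gain_test(
    wn_spike_count: int, wn_duration_s: float, baseline_rate: float
) -> tuple[float | None, float | None]:
    """DC gain (stimulation rate / spontaneous rate) and its Poisson p.

    p is the upper-tail Poisson probability of the pooled stimulation-epoch
    spike count given the expectation ``baseline_rate * duration``.  A zero
    baseline rate leaves the gain undefined (None, None).
    """
    if wn_duration_s <= 0:
        raise ValueError("duration must be positive")
    if baseline_rate < 0:
        raise ValueError("baseline rate must be non-negative")
    if baseline_rate == 0:
        return None, None
    gain = (wn_spike_count / wn_duration_s) / baseline_rate
    p = poisson_upper_tail(wn_spike_count, baseline_rate * wn_duration_s)
    return float(gain), p


def screen_unit(
    trains: SpikeTrainSet,
    baseline_rate: float,
    decoding: DecodingResult | None = None,
    reliability: ReliabilityProfile | None = None,
    alpha: float = 0.05,
    min_trials: int = 5,
    min_spikes_per_trial: float = 2.0,
) -> ScreeningReport:
    """Apply the three inclusion gates in order; short-circuit on failure.

    ``decoding`` / ``reliability`` may be omitted for units that are
    expected to fail earlier gates; reaching a gate whose result is missing
    marks the unit failed at that stage.
    """
    n_trials = trains.n_trials
    mean_spk = trains.n_spikes / n_trials if n_trials else 0.0
    report = ScreeningReport(
        unit_id=trains.unit_id, n_trials=n_trials, mean_spikes_per_trial=mean_spk,
        dc_gain=None, dc_p=None, ac_p=None, rel_p=None,
        passed=False, failure_stage="trials",
    )
    if n_trials < min_trials or mean_spk < min_spikes_per_trial:
        return report

    wn_dur = n_trials * trains.duration_ms / 1000.0
    gain, dc_p = dc_gain_test(trains.n_spikes, wn_dur, baseline_rate)
    report.dc_gain, report.dc_p = gain, dc_p
    report.failure_stage = "dc"
    if gain is None or not (gain > 1.0 and dc_p < alpha):
        return report

    report.failure_stage = "ac"
    if decoding is None or decoding.p_overall is None or not (decoding.p_overall < alpha):
        report.ac_p = None if decoding is None else decoding.p_overall
        return report
    report.ac_p = decoding.p_overall

    report.failure_stage = "reliability"
    if reliability is None or not (reliability.consistency_p < alpha):
        report.rel_p = None if reliability is None else reliability.consistency_p
        return report
    report.rel_p = reliability.consistency_p

    report.passed = True
    report.failure_stage = "none"
    return report
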