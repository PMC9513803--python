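"""End-to-end orchestration of synthetic experiments.

`run_experiment` wires the modules together: generate the stimulus, simulate
a population of units, decode every unit with the configured filter model,
screen it, and (for units passing the screens) quantify precision and the
reliability timescale.  Everything is reproducible from (config, master
seed); outputs are the plain-text formats of :mod:`wnspike.io` plus a
summary JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import io as wio
from .precision import PrecisionResult, ScreeningError, precision_sweep
from .reconstruct import DecodingResult, crossval_decode, fit_decoder
from .reliability import ReliabilityProfile, reliability_profile
from .screening import ScreeningReport, screen_unit
from .signal import StimulusTrace, generate_wn_signal, standardize
from .simulate import SimulationConfig, SpikeTrainSet, simulate_unit

__all__ = [
    "SignalSpec", "UnitSpec", "AnalysisSpec", "ExperimentConfig",
    "UnitReport", "analyze_unit", "run_experiment", "analysis_trace",
]


class SignalSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    duration_s: float = 1.0
    fs_hz: float = 6000.0
    tau_ms: float = 3.0
    fs_analysis_hz: float = 2500.0


class UnitSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    unit_id: str
    lambda1: float = 100.0
    sigma1: float = 3.0
    lambda2: float = 0.0
    sigma2: float = 0.0
    n_add: int = 0
    min_isi_ms: float = 2.0
    n_trials: int = 25
    baseline_rate: float = Field(default=2.0, description="spontaneous rate, spikes/s")


class AnalysisSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: str = "mwiener"
    causal: bool = False
    n_folds: int = 10
    n_shuffles: int = 100
    n_jitter_reps: int = 10
    alpha: float = 0.05


class ExperimentConfig(BaseModel):
    """Validated experiment description (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    signal: SignalSpec = SignalSpec()
    units: list[UnitSpec]
    analysis: AnalysisSpec = AnalysisSpec()
    seed: int = 0


@dataclass
class UnitReport:
    """Per-unit analysis summary; timing fields are populated only for the
    gates the unit passed."""

    unit_id: str
    screening: ScreeningReport
    decoding: DecodingResult | None = None
    precision: PrecisionResult | None = None
    reliability: ReliabilityProfile | None = None

    def summary(self) -> dict:
        d = {
            "unit_id": self.unit_id,
            "passed": self.screening.passed,
            "failure_stage": self.screening.failure_stage,
        }
        if self.decoding is not None:
            d["Q"] = self.decoding.Q
            d["decoding_p"] = self.decoding.p_overall
            d["time_lag_ms"] = self.decoding.time_lag_ms
        if self.precision is not None:
            d["P_ms"] = None if not self.precision.detected else self.precision.P_ms
        if self.reliability is not None:
            d["Rp_ms"] = self.reliability.Rp_ms
            d["coder_class"] = self.reliability.coder_class
        return d


def analysis_trace(spec: SignalSpec, seed: int) -> StimulusTrace:
    """Stimulus on the analysis grid: generate at the stimulation rate,
    resample, standardize."""
    raw = generate_wn_signal(spec.duration_s, spec.fs_hz, spec.tau_ms, seed)
    return standardize(raw.resample(spec.fs_analysis_hz))


def analyze_unit(
    trace_z: StimulusTrace,
    trains: SpikeTrainSet,
    baseline_rate: float,
    analysis: AnalysisSpec | None = None,
    seed: int = 0,
) -> UnitReport:
    """Decode, screen, and (if the unit passes) quantify precision and the
    reliability timescale of one unit."""
    a = analysis or AnalysisSpec()
    decoder = fit_decoder(trace_z, trains, a.kind, a.causal, a.n_folds)
    decoding = crossval_decode(
        trace_z, trains, a.kind, a.causal, a.n_folds, a.n_shuffles, seed, decoder=decoder
    )
    reliability = None
    precision = None
    if decoding.p_overall is not None and decoding.p_overall < a.alpha:
        reliability = reliability_profile(trains, fs=trace_z.fs, alpha=a.alpha)
        try:
            precision = precision_sweep(
                trace_z, trains, a.kind, a.causal, a.n_folds, a.n_jitter_reps,
                seed=seed, alpha=a.alpha, decoding=decoding, decoder=decoder,
            )
        except ScreeningError:
            precision = None
    screening = screen_unit(
        trains, baseline_rate, decoding=decoding, reliability=reliability, alpha=a.alpha
    )
    return UnitReport(
        unit_id=trains.unit_id, screening=screening, decoding=decoding,
        precision=precision, reliability=reliability,
    )


def run_experiment(config: ExperimentConfig, outdir) -> list[UnitReport]:
    """Simulate and analyze every configured unit; write spike tables,
    per-unit reports, and a summary JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trace_z = analysis_trace(config.signal, config.seed)
    reports = []
    all_trains = []
    for k, u in enumerate(config.units):
        cfg = SimulationConfig(
            fs=config.signal.fs_analysis_hz, n_trials=u.n_trials,
            duration=config.signal.duration_s, lambda1=u.lambda1, sigma1=u.sigma1,
            lambda2=u.lambda2, sigma2=u.sigma2, n_add=u.n_add,
            min_isi=u.min_isi_ms, seed=config.seed * 10007 + k,
        )
        trains = simulate_unit(cfg, trace_z, unit_id=u.unit_id)
        all_trains.append(trains)
        rep = analyze_unit(trace_z, trains, u.baseline_rate, config.analysis,
                           seed=config.seed * 10007 + k)
        reports.append(rep)
        if rep.reliability is not None:
            wio.write_profile_tsv(rep.reliability, outdir / f"{u.unit_id}_profile.tsv")
        if rep.decoding is not None:
            wio.write_decoding_json(rep.decoding, outdir / f"{u.unit_id}_decoding.json")
    wio.write_spike_table(all_trains, outdir / "spikes.tsv",
                          config=json.loads(config.model_dump_json()))
    summary = {"seed": config.seed, "units": [r.summary() for r in reports]}
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return reports
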