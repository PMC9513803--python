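"""Plain-text serialization of the package's data objects.

Formats:

* signal TSV — ``t_ms<TAB>value`` with a header line
  ``# fs_hz=<int> tau_ms=<float> seed=<int> standardized=<0|1>``; the
  round-trip is lossless to well below 1e-9 (values printed at 17
  significant digits).
* spike table TSV — ``unit_id<TAB>trial_id<TAB>t_ms`` (trial-relative ms,
  0-based trials), optional JSON sidecar with the generating config.
* decoding / precision / profile reports — JSON and TSV as documented on
  each writer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .reconstruct import DecodingResult, FilterModel
from .signal import StimulusTrace
from .simulate import SpikeTrainSet

__all__ = [
    "write_signal_tsv", "read_signal_tsv",
    "write_spike_table", "read_spike_table",
    "write_decoding_json", "write_filter_tsv",
    "write_profile_tsv", "write_pair_table",
]


def write_signal_tsv(trace: StimulusTrace, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"# fs_hz={int(round(trace.fs))} tau_ms={trace.tau!r} "
            f"seed={trace.seed} standardized={int(trace.standardized)}\n"
        )
        fh.write("t_ms\tvalue\n")
        for t, v in zip(trace.times_ms, trace.samples):
            fh.write(f"{t:.9g}\t{v:.17g}\n")


def read_signal_tsv(path) -> StimulusTrace:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise ValueError(f"{path}: missing signal header line")
    meta = dict(kv.split("=") for kv in header[1:].split())
    df = pd.read_csv(path, sep="\t", comment=None, skiprows=1)
    return StimulusTrace(
        samples=df["value"].to_numpy(),
        fs=float(meta["fs_hz"]),
        tau=float(meta["tau_ms"]),
        seed=int(meta["seed"]),
        standardized=bool(int(meta["standardized"])),
    )


def write_spike_table(trains_list, path, config: dict | None = None) -> None:
    """Write one or more SpikeTrainSets to a single spike-table TSV."""
    if isinstance(trains_list, SpikeTrainSet):
        trains_list = [trains_list]
    path = Path(path)
    rows = []
    for ts in trains_list:
        for k, t in enumerate(ts.trials):
            for x in t:
                rows.append((ts.unit_id, k, x))
    df = pd.DataFrame(rows, columns=["unit_id", "trial_id", "t_ms"])
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(config, indent=1, default=_jsonable))


def read_spike_table(path, duration_ms: float, n_trials: int | None = None) -> dict[str, SpikeTrainSet]:
    """Read a spike-table TSV into SpikeTrainSets keyed by unit id.

    ``n_trials`` forces the trial count (trailing empty trials are
    otherwise invisible in the table)."""
    df = pd.read_csv(Path(path), sep="\t", dtype={"unit_id": str})
    out = {}
    for uid, g in df.groupby("unit_id", sort=True):
        nt = n_trials if n_trials is not None else int(g["trial_id"].max()) + 1
        trials = [np.empty(0)] * nt
        hi = np.nextafter(duration_ms, 0.0)
        for k, gg in g.groupby("trial_id"):
            t = np.sort(gg["t_ms"].to_numpy(dtype=float))
            # printed precision may round a time up to the trial end
            trials[int(k)] = np.minimum(t, hi)
        out[str(uid)] = SpikeTrainSet(unit_id=str(uid), trials=trials, duration_ms=duration_ms)
    return out


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    return str(obj)


def write_decoding_json(result: DecodingResult, path) -> None:
    payload = {
        "unit_id": result.unit_id,
        "kind": result.kind,
        "causal": result.causal,
        "Q": result.Q,
        "p": result.p_overall,
        "time_lag_ms": result.time_lag_ms,
        "q_trials": [None if not np.isfinite(q) else float(q) for q in result.q_trials],
        "n_folds": result.n_folds,
        "n_excluded": result.n_excluded,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_filter_tsv(filt: FilterModel, path) -> None:
    """Filter coefficients as ``lag_ms<TAB>coef`` (bank rows as extra columns)."""
    coefs = np.atleast_2d(filt.coefficients)
    cols = {"lag_ms": filt.lags_ms}
    for i, row in enumerate(coefs):
        cols["coef" if coefs.shape[0] == 1 else f"coef_bin{i}"] = row
    pd.DataFrame(cols).to_csv(Path(path), sep="\t", index=False, float_format="%.9g")


def write_profile_tsv(profile, path) -> None:
    """Reliability profile: ``sigma_ms<TAB>r_mean<TAB>r_sem<TAB>n_pairs``."""
    sem = [
        np.std(p, ddof=1) / np.sqrt(len(p)) if len(p) > 1 else 0.0 for p in profile.r_pairs
    ]
    df = pd.DataFrame({
        "sigma_ms": profile.sigmas,
        "r_mean": profile.r_values,
        "r_sem": sem,
        "n_pairs": [len(p) for p in profile.r_pairs],
    })
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.9g")


def write_pair_table(curves, path) -> None:
    """Connectivity pair table:
    ``pre_id<TAB>post_id<TAB>gain<TAB>peak_lag_ms<TAB>p<TAB>significant``."""
    rows = [
        (c.pre_id, c.post_id, c.gain, c.peak_lag_ms, c.p_value, int(c.significant))
        for c in curves
    ]
    df = pd.DataFrame(rows, columns=["pre_id", "post_id", "gain", "peak_lag_ms", "p", "significant"])
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.9g")
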