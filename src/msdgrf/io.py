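"""Plain-text file formats.

Trials are 2-column CSV (``time_s,value``) with a JSON sidecar carrying
unit, sample rate and trial metadata; parameter sets and fit results are
JSON.  The sidecar shares the CSV's basename with a ``.json`` suffix.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .fitting import FitResult
from .model import PARAM_NAMES, ScaledParameters
from .signals import TrialSeries
from .synthetic import SyntheticTrial


def write_series(path, series: TrialSeries, meta: Optional[dict] = None) -> None:
    """Write a series as ``time_s,value`` CSV plus a JSON sidecar."""
    path = Path(path)
    frame = pd.DataFrame({"time_s": series.times, "value": series.values})
    frame.to_csv(path, index=False, float_format="%.10g")
    sidecar = {"unit": series.unit, "rate_hz": series.rate, "t0_s": series.t0}
    sidecar.update(meta or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_series(path) -> tuple[TrialSeries, dict]:
    """Read a series CSV and its sidecar; returns (series, sidecar)."""
    path = Path(path)
    frame = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    t = frame["time_s"].to_numpy()
    rate = float(sidecar["rate_hz"])
    series = TrialSeries(
        t0=float(sidecar.get("t0_s", t[0] if t.size else 0.0)),
        rate=rate,
        values=frame["value"].to_numpy(),
        unit=sidecar["unit"],
    )
    return series, sidecar


def write_params(path, params: ScaledParameters) -> None:
    payload = {n: getattr(params, n) for n in PARAM_NAMES if n != "lam"}
    payload["lambda"] = params.lam
    payload["mass_kg"] = params.M
    Path(path).write_text(json.dumps(payload, indent=2))


def read_params(path) -> ScaledParameters:
    payload = json.loads(Path(path).read_text())
    kwargs = {n: float(payload[n]) for n in PARAM_NAMES if n != "lam"}
    return ScaledParameters(lam=float(payload["lambda"]), M=float(payload["mass_kg"]), **kwargs)


def write_fit_result(path, result: FitResult) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2))


def write_cohort(out_dir, trials: Sequence[SyntheticTrial]) -> Path:
    """Write per-trial CSV pairs plus a manifest of metadata and truth
    parameters; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in trials:
        base = out_dir / trial.trial_id
        meta = {
            "mass_kg": trial.mass,
            "speed_ms": trial.speed,
            "speed_nominal_ms": trial.speed_nominal,
            "subject_id": trial.subject_id,
            "trial_id": trial.trial_id,
            "seed": trial.seed,
        }
        write_series(base.with_name(base.name + "_grf.csv"), trial.grf, meta)
        write_series(base.with_name(base.name + "_acc.csv"), trial.trunk_acc, meta)
        row = dict(meta)
        for n in PARAM_NAMES:
            row[f"truth_{n}"] = getattr(trial.truth, n)
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
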