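"""Reading and writing the pipeline's tabular and JSON formats.

Conventions: CSV with a mandatory header row; clock times stored as
decimal hours (8.25 = 08:15), with ISO timestamps accepted and converted
on read; JSON for models, weights, configs and manifests; JSON-lines for
event streams; pulse traces as two-column CSV (time_s, value) with a
JSON sidecar carrying the sample rate and, for synthetic traces, the
ground-truth beat times.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import BIOMARKERS, PulseTrace
from .errors import SchemaError

PANEL_COLUMNS = ("subject_id", "time", "cortisol", "glucose", "st", "hr")


def _clock_hours(raw: pd.Series) -> pd.Series:
    """Decimal clock hours from either numeric strings or ISO timestamps."""
    as_num = pd.to_numeric(raw, errors="coerce")
    out = as_num.copy()
    iso_mask = as_num.isna() & raw.notna()
    if iso_mask.any():
        ts = pd.to_datetime(raw[iso_mask], errors="coerce")
        out[iso_mask] = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    return out


def read_panel(path) -> pd.DataFrame:
    """Read and validate a biomarker panel CSV.

    Schema: subject_id,time,cortisol,glucose,st,hr. Missing columns,
    non-numeric biomarker values and non-positive biomarker values are
    reported with the offending column and 1-based file line number
    (header = line 1).
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    problems = []
    df["time"] = _clock_hours(df["time"])
    if df["time"].isna().any():
        for i in df.index[df["time"].isna()]:
            problems.append(f"line {i + 2}: unparseable time")
    for col in BIOMARKERS:
        vals = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[vals.isna()]:
            problems.append(f"line {i + 2}: non-numeric {col}")
        bad = vals.notna() & (vals <= 0)
        for i in df.index[bad]:
            problems.append(f"line {i + 2}: non-positive {col} ({vals[i]})")
        df[col] = vals
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    return df[list(PANEL_COLUMNS)]


def write_panel(df: pd.DataFrame, path) -> None:
    df[list(PANEL_COLUMNS)].to_csv(path, index=False)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str})


def write_jsonl(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def read_jsonl(path) -> list:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_pulse_trace(trace: PulseTrace, csv_path) -> None:
    """Two-column CSV plus a JSON sidecar (<csv>.json)."""
    csv_path = Path(csv_path)
    pd.DataFrame({"time_s": trace.times, "value": trace.values}).to_csv(
        csv_path, index=False)
    sidecar = {"sample_rate": trace.sample_rate,
               "true_beat_times": np.asarray(trace.true_beat_times).tolist()}
    with open(csv_path.with_suffix(csv_path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh)


def read_pulse_trace(csv_path, sample_rate: float | None = None) -> PulseTrace:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    if "value" not in df.columns:
        raise SchemaError(f"{csv_path}: expected columns time_s,value")
    sidecar_path = csv_path.with_suffix(csv_path.suffix + ".json")
    beats = np.empty(0)
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        sample_rate = sample_rate or sidecar.get("sample_rate")
        beats = np.asarray(sidecar.get("true_beat_times", []), dtype=float)
    if sample_rate is None:
        if "time_s" not in df.columns or len(df) < 2:
            raise SchemaError(f"{csv_path}: cannot infer sample rate")
        sample_rate = 1.0 / float(np.median(np.diff(df["time_s"])))
    return PulseTrace(sample_rate=float(sample_rate),
                      values=df["value"].to_numpy(dtype=float),
                      true_beat_times=beats)


def load_config_file(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh)
        return json.load(fh)


def dump_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
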