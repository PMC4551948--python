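"""File formats: trace CSV, anisotropy CSV, fit-result JSON, study config.

Trace CSV columns: ``time_s,Ip_counts,Is_counts[,dead]`` (UTF-8, comma
separated); the bin width is inferred from the time spacing and checked
uniform.  Anisotropy CSV columns: ``time_s,r,r_err``.  Configs are YAML or
JSON with the same schema.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult
from .traces import AnisotropyCurve, PolarizedTrace

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_anisotropy_csv",
    "write_anisotropy_csv",
    "fit_result_to_dict",
    "write_fit_result_json",
    "load_config",
]

_TRACE_COLS = ("time_s", "Ip_counts", "Is_counts")


def read_trace_csv(path) -> PolarizedTrace:
    """Parse and validate a dual-channel trace CSV.

    Raises ``ValueError`` with the offending row and column named for
    negative counts, missing columns, or non-uniform time spacing.
    """
    df = pd.read_csv(path)
    missing = [c for c in _TRACE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("Ip_counts", "Is_counts"):
        bad = np.flatnonzero(df[col].to_numpy() < 0)
        if bad.size:
            raise ValueError(
                f"{path}: negative count at row {bad[0] + 1}, column {col}"
            )
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least 2 bins to infer the bin width")
    dt = np.diff(t)
    raw_bin = float(np.median(dt))
    if raw_bin <= 0 or not np.allclose(dt, raw_bin, rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: time_s spacing is not uniform")
    dead = None
    if "dead" in df.columns:
        dead = df["dead"].to_numpy().astype(bool)
    try:
        return PolarizedTrace(
            time_s=t,
            Ip=df["Ip_counts"].to_numpy(dtype=float),
            Is=df["Is_counts"].to_numpy(dtype=float),
            raw_bin=raw_bin,
            dead=dead,
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_trace_csv(trace: PolarizedTrace, path) -> None:
    """Write a trace CSV (deterministic formatting; counts as integers when
    integral, the dead column only when any bin is flagged)."""
    cols: dict = {"time_s": [f"{t:.6f}" for t in trace.time_s]}
    for name, arr in (("Ip_counts", trace.Ip), ("Is_counts", trace.Is)):
        if np.all(arr == np.floor(arr)):
            cols[name] = arr.astype(np.int64)
        else:
            cols[name] = [f"{v:.10g}" for v in arr]
    df = pd.DataFrame(cols)
    if np.any(trace.dead):
        df["dead"] = trace.dead.astype(int)
    df.to_csv(path, index=False)


def read_anisotropy_csv(path) -> AnisotropyCurve:
    df = pd.read_csv(path)
    missing = [c for c in ("time_s", "r", "r_err") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    width = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    return AnisotropyCurve(
        time_s=t,
        r=df["r"].to_numpy(dtype=float),
        r_err=df["r_err"].to_numpy(dtype=float),
        bin_width=width,
    )


def write_anisotropy_csv(curve: AnisotropyCurve, path, only_usable: bool = True) -> None:
    if only_usable:
        t, r, err = curve.usable()
    else:
        t, r, err = curve.time_s, curve.r, curve.r_err
    pd.DataFrame({"time_s": t, "r": r, "r_err": err}).to_csv(path, index=False)


def fit_result_to_dict(res: FitResult) -> dict:
    d = dataclasses.asdict(res)
    if d["cov"] is not None:
        d["cov"] = np.asarray(d["cov"]).tolist()
    return d


def write_fit_result_json(res: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(res), indent=1))


def load_config(path) -> dict:
    """Load a study config from YAML or JSON (by extension)."""
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)
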