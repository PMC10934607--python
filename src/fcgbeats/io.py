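"""Reading and writing signals, tachograms and result JSON files.

Signal CSV dialect: comma separator, '.' decimal, UTF-8, one header line;
either two columns ``time_s,value`` or a single ``value`` column with the
sampling rate supplied separately.  Timestamps in JSON outputs are seconds
with 6 decimals, intervals milliseconds with 3 decimals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import InvalidArgumentError, Tachogram, UniformSignal
from .synth import GroundTruth

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "read_tachogram_csv",
    "write_tachogram_csv",
    "read_truth_json",
    "write_truth_json",
    "write_json",
    "validate_output",
    "OUTPUT_SCHEMAS",
]

# fraction of the median sampling interval tolerated as time-axis deviation
_UNIFORMITY_TOL = 0.01


class FormatError(ValueError):
    """A file violates the documented CSV/JSON contract."""


def _check_numeric(frame: pd.DataFrame, path: str) -> pd.DataFrame:
    for col in frame.columns:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = vals.isna() & frame[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise FormatError(f"{path}: non-numeric value in column {col!r} at data row {row}")
        if vals.isna().any():
            row = int(np.nonzero(vals.isna().to_numpy())[0][0])
            raise FormatError(f"{path}: missing value in column {col!r} at data row {row}")
        # re-parse through Python's float() for exact (round-trip) precision
        frame[col] = np.array([float(v) for v in frame[col]], dtype=float)
    return frame


def read_signal_csv(path: str | Path, fs: float | None = None) -> UniformSignal:
    """Load a signal CSV, validating that the time axis is uniform.

    A ``time_s`` column must advance by a constant step (deviations beyond
    1% of the median step are rejected, naming the first offending row).
    Without a time column, ``fs`` must be given.
    """
    frame = pd.read_csv(path, dtype=str)
    cols = [c.strip() for c in frame.columns]
    frame.columns = cols
    if "time_s" in cols and "value" in cols:
        frame = _check_numeric(frame[["time_s", "value"]], str(path))
        t = frame["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if dt.size == 0:
            raise FormatError(f"{path}: need at least 2 samples")
        med = float(np.median(dt))
        if med <= 0:
            raise FormatError(f"{path}: time column must be increasing")
        dev = np.abs(dt - med)
        if np.any(dev >= _UNIFORMITY_TOL * med):
            row = int(np.argmax(dev >= _UNIFORMITY_TOL * med)) + 1
            raise FormatError(f"{path}: non-uniform sampling at data row {row}")
        return UniformSignal(frame["value"].to_numpy(dtype=float), fs=1.0 / med, t0=float(t[0]))
    if "value" in cols:
        if fs is None:
            raise InvalidArgumentError("single-column CSV requires a sampling rate")
        frame = _check_numeric(frame[["value"]], str(path))
        return UniformSignal(frame["value"].to_numpy(dtype=float), fs=fs)
    raise FormatError(f"{path}: expected columns 'time_s,value' or 'value'")


def write_signal_csv(sig: UniformSignal, path: str | Path) -> None:
    """Write a two-column signal CSV (full-precision values)."""
    t = sig.times
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_s,value\n")
        for ti, vi in zip(t, sig.samples):
            fh.write(f"{ti:.9f},{float(vi)!r}\n")


def read_tachogram_csv(path: str | Path) -> Tachogram:
    """Load a tachogram CSV with columns ``time_s,rr_ms``."""
    frame = pd.read_csv(path)
    if not {"time_s", "rr_ms"}.issubset(frame.columns):
        raise FormatError(f"{path}: expected columns 'time_s,rr_ms'")
    return Tachogram(
        intervals=frame["rr_ms"].to_numpy(dtype=float),
        times=frame["time_s"].to_numpy(dtype=float),
    )


def write_tachogram_csv(tacho: Tachogram, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_s,rr_ms\n")
        for t, rr in zip(tacho.times, tacho.intervals):
            fh.write(f"{t:.6f},{rr:.3f}\n")


def read_truth_json(path: str | Path) -> GroundTruth:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    return GroundTruth(
        r_times=np.asarray(data["r_times"], dtype=float),
        s1_times=np.asarray(data["s1_times"], dtype=float),
        s2_times=np.asarray(data["s2_times"], dtype=float),
    )


def write_truth_json(truth: GroundTruth, path: str | Path) -> None:
    write_json(
        {
            "r_times": [round(float(v), 6) for v in truth.r_times],
            "s1_times": [round(float(v), 6) for v in truth.s1_times],
            "s2_times": [round(float(v), 6) for v in truth.s2_times],
        },
        path,
    )


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# Lightweight output contracts: required keys (and per-label sub-keys) of
# each JSON the pipeline writes.  Kept in the package so tests and users can
# validate files without an external schema dependency.
OUTPUT_SCHEMAS: dict[str, dict] = {
    "events": {"required": ["S1", "S2", "S1S2"], "item": list},
    "stats": {
        "required": ["S1", "S2", "S1S2"],
        "item_keys": ["tp", "fp", "fn", "sensitivity_pct", "ppv_pct", "n_reference"],
    },
    "agreement": {
        "required": ["S1", "S2", "S1S2"],
        "item_keys": ["n", "r", "r_ci", "slope", "slope_ci", "intercept_ms",
                      "intercept_ci_ms", "cusum_linear", "bias_ms", "loa_low_ms",
                      "loa_high_ms", "normal"],
    },
    "hrv": {
        "required": ["reference"],
        "item_keys": ["mean_rr", "sdnn", "rmssd", "nn50", "pnn50", "sd1", "sd2"],
    },
}


def validate_output(kind: str, obj: dict) -> None:
    """Check a result object against its published contract.

    Raises :class:`FormatError` on a missing section or field.
    """
    schema = OUTPUT_SCHEMAS[kind]
    for key in schema["required"]:
        if key not in obj:
            raise FormatError(f"{kind}: missing section {key!r}")
        if "item_keys" in schema:
            for sub in schema["item_keys"]:
                if sub not in obj[key]:
                    raise FormatError(f"{kind}.{key}: missing field {sub!r}")
        elif "item" in schema and not isinstance(obj[key], schema["item"]):
            raise FormatError(f"{kind}.{key}: expected {schema['item'].__name__}")
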