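"""CSV/JSON input and output.

File conventions: glucose in mg/dL, times in minutes from run start,
UTF-8, decimal point.  Paired CSV columns: ``time_min,cgm_mgdl,ref_mgdl``;
trace CSV columns: ``time_min,glucose_mgdl``.  Reports round numbers to six
significant digits and use a deterministic field order, so identical results
produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Union

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .metrics import GlucoseTrace, PairedDataset

PAIRED_COLUMNS = ["time_min", "cgm_mgdl", "ref_mgdl"]
TRACE_COLUMNS = ["time_min", "glucose_mgdl"]


def _read_validated(path, columns) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"file not found: {path}")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing required columns {missing}")
    out = {}
    bad_lines = set()
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna()]
        bad_lines.update(int(i) + 2 for i in bad)  # +2: header + 1-based
        out[col] = converted
    if bad_lines:
        raise InvalidInputError(
            f"{path}: non-numeric or missing cells on lines {sorted(bad_lines)}"
        )
    return pd.DataFrame(out)


def read_paired_csv(path) -> PairedDataset:
    """Read and validate a paired-measurement CSV."""
    df = _read_validated(path, PAIRED_COLUMNS)
    nonpos = df.index[df["ref_mgdl"] <= 0]
    if len(nonpos):
        lines = [int(i) + 2 for i in nonpos]
        raise InvalidInputError(
            f"{path}: non-positive reference values on lines {lines}"
        )
    return PairedDataset(
        times=df["time_min"].to_numpy(),
        cgm_values=df["cgm_mgdl"].to_numpy(),
        ref_values=df["ref_mgdl"].to_numpy(),
    )


def write_paired_csv(paired: PairedDataset, path) -> None:
    paired.to_frame().to_csv(path, index=False)


def read_trace_csv(path, label: str = "BG") -> GlucoseTrace:
    """Read a uniformly sampled trace CSV; the grid spacing must be constant."""
    df = _read_validated(path, TRACE_COLUMNS)
    t = df["time_min"].to_numpy()
    if len(t) < 2:
        raise InvalidInputError(f"{path}: trace needs at least 2 samples")
    dt = np.diff(t)
    if np.any(np.abs(dt - dt[0]) > 1e-6):
        raise InvalidInputError(f"{path}: sampling interval is not constant")
    return GlucoseTrace(
        values=df["glucose_mgdl"].to_numpy(),
        sampling_interval=float(dt[0]),
        start_time=float(t[0]),
        label=label,
    )


def write_trace_csv(trace: GlucoseTrace, path) -> None:
    pd.DataFrame(
        {"time_min": trace.times, "glucose_mgdl": trace.values}
    ).to_csv(path, index=False)


def _round6(x: float) -> float:
    return float(f"{x:.6g}")


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return {
            "columns": list(map(str, obj.columns)),
            "rows": [[_jsonable(v) for v in row] for row in obj.itertuples(index=False)],
        }
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else _round6(v)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _flatten(d: Any, prefix: str = "") -> dict:
    out = {}
    if isinstance(d, dict):
        for k, v in d.items():
            out.update(_flatten(v, f"{prefix}{k}."))
    else:
        out[prefix.rstrip(".")] = d
    return out


def write_report(results: Any, format: str = "json", path: Union[str, Path] = None) -> str:
    """Serialize a result object (dataclass, dict, DataFrame) to JSON or CSV.

    Returns the serialized text; also writes it to ``path`` when given.
    Scalars are rounded to 6 significant digits; field order follows the
    dataclass/dict definition, so output is deterministic.
    """
    data = _jsonable(results)
    if format == "json":
        text = json.dumps(data, indent=2) + "\n"
    elif format == "csv":
        if isinstance(results, pd.DataFrame):
            df = results.copy()
            for col in df.select_dtypes(include=[float]).columns:
                df[col] = df[col].map(lambda v: _round6(v) if np.isfinite(v) else "")
            text = df.to_csv(index=False)
        else:
            flat = _flatten(data)
            scalars = {
                k: v for k, v in flat.items() if not isinstance(v, (list, dict))
            }
            text = ",".join(scalars) + "\n" + ",".join(str(v) for v in scalars.values()) + "\n"
    else:
        raise InvalidInputError(f"unknown report format {format!r}")
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
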