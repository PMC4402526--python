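"""Plain-text I/O for traces, force-velocity tables and fit reports.

Traces are 3-column tab-delimited text (time_s, delta_x_nm, force_pN) with
a JSON sidecar (same stem, ``.json``) holding the generating configuration
and ground-truth annotations.  Force-velocity tables are 4-column delimited
text (force_pN, dntp_uM, velocity_nt_s, sem_nt_s); the replicate count
travels in the sidecar.  No binary formats: there is no community standard
for tweezers records, and delimited text keeps everything inspectable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .traces import ReplicationTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_fv",
    "read_fv",
    "write_json_report",
]

_TRACE_COLUMNS = ["time_s", "delta_x_nm", "force_pN"]
_FV_COLUMNS = ["force_pN", "dntp_uM", "velocity_nt_s", "sem_nt_s"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_trace(trace: ReplicationTrace, path) -> Path:
    """Write a trace as TSV plus a JSON sidecar of its annotations."""
    path = Path(path)
    df = pd.DataFrame({
        "time_s": trace.time,
        "delta_x_nm": trace.delta_x,
        "force_pN": trace.force,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    sidecar = {k: _jsonable(v) for k, v in trace.annotations.items()
               if k != "true_nt"}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_trace(path) -> ReplicationTrace:
    """Read a trace written by :func:`write_trace` (sidecar optional)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+", comment="#")
    except Exception as exc:
        raise ValueError(f"cannot parse trace file {path}: {exc}") from exc
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    annotations = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        annotations = json.loads(sidecar.read_text())
        if "pauses" in annotations:
            annotations["pauses"] = [tuple(p) for p in annotations["pauses"]]
    return ReplicationTrace(
        time=df["time_s"].to_numpy(float),
        delta_x=df["delta_x_nm"].to_numpy(float),
        force=df["force_pN"].to_numpy(float),
        annotations=annotations,
    )


def write_fv(dataset: pd.DataFrame, path, sidecar: dict | None = None) -> Path:
    """Write a force-velocity table (4 columns, tab-delimited)."""
    path = Path(path)
    dataset[_FV_COLUMNS].to_csv(path, sep="\t", index=False,
                                float_format="%.8g")
    if sidecar is not None:
        meta = dict(sidecar)
        if "n" in dataset.columns:
            meta.setdefault("n_replicates", int(dataset["n"].iloc[0]))
        path.with_suffix(".json").write_text(json.dumps(_jsonable(meta),
                                                        indent=1))
    return path


def read_fv(path) -> pd.DataFrame:
    """Read a force-velocity table; restores the replicate count if known."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+", comment="#")
    except Exception as exc:
        raise ValueError(f"cannot parse FV file {path}: {exc}") from exc
    missing = [c for c in _FV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sidecar = path.with_suffix(".json")
    if sidecar.exists() and "n" not in df.columns:
        meta = json.loads(sidecar.read_text())
        if "n_replicates" in meta:
            df["n"] = meta["n_replicates"]
    return df


def write_json_report(obj, path) -> Path:
    """Serialize a report-like object (dataclass dict / mapping) to JSON."""
    path = Path(path)
    if hasattr(obj, "to_dict"):
        obj = obj.to_dict()
    path.write_text(json.dumps(_jsonable(obj), indent=1))
    return path
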