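"""Readers and writers for the pipeline's CSV/JSON interchange formats."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import RawTrace

TRACE_HEADER = ["t", "ax", "ay", "az"]


class TraceFormatError(ValueError):
    pass


def write_trace_csv(trace: RawTrace, path, t0: float = 0.0) -> None:
    """Write a trace as ``t,ax,ay,az`` (s and m/s^2, full float precision)."""
    t = t0 + np.arange(len(trace)) / trace.fs
    df = pd.DataFrame({"t": t, "ax": trace.data[:, 0],
                       "ay": trace.data[:, 1], "az": trace.data[:, 2]})
    df.to_csv(path, index=False, float_format="%.12g")


def read_trace_csv(path) -> RawTrace:
    """Read a ``t,ax,ay,az`` trace, inferring fs from the time column.

    Rejects malformed headers, non-monotone time, non-uniform sampling
    (>1% spread in dt) and non-finite values, each with a distinct message.
    """
    df = pd.read_csv(path)
    if list(df.columns) != TRACE_HEADER:
        raise TraceFormatError(
            f"malformed header in {path}: expected {TRACE_HEADER}, got {list(df.columns)}")
    values = df.to_numpy(float)
    if not np.all(np.isfinite(values)):
        raise TraceFormatError(f"non-finite values in {path}")
    t = values[:, 0]
    if len(t) < 2:
        raise TraceFormatError(f"trace {path} too short (need >= 2 samples)")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise TraceFormatError(f"non-monotone time column in {path}")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > 0.01 * med:
        raise TraceFormatError(f"non-uniform sampling in {path} (>1% jitter in dt)")
    return RawTrace(fs=1.0 / med, data=values[:, 1:4])


def write_ground_truth_json(gt, path) -> None:
    payload = {
        "ic_times": {side: list(map(float, times)) for side, times in gt.ic_times.items()},
        "true_mean_speed": gt.true_mean_speed,
        "stride_durations": list(map(float, gt.stride_durations)),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, config: dict, inputs: list, stages: dict) -> None:
    """Run manifest: config hash, input checksums, package version, QC."""
    from . import __version__

    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()
    manifest = {
        "package_version": __version__,
        "config": config,
        "config_sha256": cfg_hash,
        "inputs": [{"file": str(p), "sha256": file_sha256(p)} for p in inputs],
        "stages": stages,
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
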