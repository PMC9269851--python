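"""The whole-body gait Symmetry Index.

Pearson's correlation r between the mean normalized left- and right-cycle
AP waveforms, remapped from [-1, 1] to a 0-100 scale:

    SI = (r + 1) * 100 / 2

SI = 100 means the trunk accelerates identically over left and right
strides; SI = 0 means exactly anti-correlated waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import preprocess, segmentation
from .preprocess import RawTrace
from .segmentation import SideMeanWaveform

R_CLAMP_TOL = 1e-12


class SymmetryError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    """A processing stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r}: {original}")
        self.stage = stage
        self.original = original


@dataclass
class SymmetryResult:
    r: float
    si: float
    n_left: int
    n_right: int
    participant_id: str | None = None
    condition: str | None = None
    trial: int | None = None
    left_mean: np.ndarray | None = None
    right_mean: np.ndarray | None = None
    qc: dict = field(default_factory=dict)


def pearson_r(left: SideMeanWaveform | np.ndarray,
              right: SideMeanWaveform | np.ndarray) -> float:
    """Pearson product-moment correlation of the two side-mean waveforms."""
    l = np.asarray(left.waveform if isinstance(left, SideMeanWaveform) else left, float)
    r = np.asarray(right.waveform if isinstance(right, SideMeanWaveform) else right, float)
    if l.shape != r.shape:
        raise SymmetryError(f"waveform lengths differ: {l.shape} vs {r.shape}")
    lc, rc = l - l.mean(), r - r.mean()
    denom2 = float(lc @ lc) * float(rc @ rc)
    if denom2 == 0.0:
        raise SymmetryError("zero-variance waveform: correlation undefined")
    return float(lc @ rc) / np.sqrt(denom2)


def symmetry_index(r: float) -> float:
    """Remap r in [-1, 1] to the 0-100 symmetry scale: (r + 1) * 100 / 2."""
    if not np.isfinite(r):
        raise SymmetryError("r must be finite")
    if abs(r) > 1.0 + R_CLAMP_TOL:
        raise SymmetryError(f"|r| = {abs(r)} exceeds 1 beyond numerical tolerance")
    r = float(np.clip(r, -1.0, 1.0))
    return (r + 1.0) * 100.0 / 2.0


def compute_trial_si(trace: RawTrace, config=None, **meta) -> SymmetryResult:
    """Run the full per-trial chain from a raw sensor-frame trace to SI.

    filter -> tilt -> earth frame -> AP -> contacts -> tilt refinement on the
    integer-stride window -> sides -> edge trim -> cycles -> time
    normalization -> side means -> Pearson r -> SI.

    The tilt refinement re-estimates the gravity direction over the window
    between the first and last detected contact, where the periodic gait
    components average out exactly, and redoes the rotation.
    """
    from .config import PipelineConfig

    cfg = config or PipelineConfig()
    qc: dict = {}

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineStageError(name, exc) from exc

    filt = stage("lowpass_filter", preprocess.lowpass_filter, trace,
                 cfg.filter_cutoff_hz, cfg.filter_order)
    tilt = stage("estimate_tilt", preprocess.estimate_tilt, filt)
    earth = stage("to_earth_frame", preprocess.to_earth_frame, filt, tilt)
    ap = preprocess.extract_ap(earth)
    events = stage("detect_initial_contacts", segmentation.detect_initial_contacts,
                   ap, earth.v, trace.fs, cfg.detector_k_mad,
                   cfg.detector_min_separation_frac, cfg.detector_prominence_floor)
    qc["n_events"] = len(events)

    # refine tilt on the integer-stride window between first and last contact
    window = slice(events[0].sample_index, events[-1].sample_index)
    if window.stop - window.start > trace.fs:
        tilt = stage("estimate_tilt", preprocess.estimate_tilt, filt, window)
        earth = stage("to_earth_frame", preprocess.to_earth_frame, filt, tilt)
        ap = preprocess.extract_ap(earth)
    qc["tilt_pitch_rad"] = tilt.pitch
    qc["tilt_roll_rad"] = tilt.roll

    events = stage("label_sides", segmentation.label_sides, events, earth.ml,
                   trace.fs, cfg.side_window_s, cfg.ml_positive_is_right,
                   cfg.ml_floor)
    events = stage("trim_edge_events", segmentation.trim_edge_events, events,
                   cfg.trim_events)
    cycles = stage("split_cycles", segmentation.split_cycles, events, trace.fs,
                   cfg.duration_gate)
    normalized = [stage("time_normalize", segmentation.time_normalize, ap, c, cfg.n_points)
                  for c in cycles]
    qc["n_cycles"] = len(normalized)
    left = stage("mean_waveform", segmentation.mean_waveform, normalized, "left",
                 cfg.min_cycles)
    right = stage("mean_waveform", segmentation.mean_waveform, normalized, "right",
                  cfg.min_cycles)
    qc["low_cycle_count"] = len(normalized) < cfg.min_cycles
    r = stage("pearson_r", pearson_r, left, right)
    si = stage("symmetry_index", symmetry_index, r)
    return SymmetryResult(r=r, si=si, n_left=left.n_cycles, n_right=right.n_cycles,
                          left_mean=left.waveform, right_mean=right.waveform,
                          qc=qc, **meta)


def aggregate_si(results, strategy: str = "mean-of-trials"):
    """One SI per participant x condition from that condition's trials.

    ``mean-of-trials``: arithmetic mean of the trial SIs (default).
    ``pool-cycles``: cycle-count-weighted mean of the side waveforms across
    trials, then one Pearson r / SI on the pooled means.
    Participants missing a condition yield a flagged (NaN) row, not a drop.
    """
    import pandas as pd

    if strategy not in ("mean-of-trials", "pool-cycles"):
        raise SymmetryError(f"unknown aggregation strategy {strategy!r}")
    rows = []
    by_key: dict[tuple, list[SymmetryResult]] = {}
    participants: dict[str, set] = {}
    for res in results:
        by_key.setdefault((res.participant_id, res.condition), []).append(res)
        participants.setdefault(res.participant_id, set()).add(res.condition)
    all_conditions = sorted({c for conds in participants.values() for c in conds})
    for pid, conds in participants.items():
        for condition in all_conditions:
            group = by_key.get((pid, condition))
            if not group:
                rows.append({"participant_id": pid, "condition": condition,
                             "si": np.nan, "n_trials": 0, "flag": "missing-condition"})
                continue
            if strategy == "mean-of-trials":
                si = float(np.mean([g.si for g in group]))
            else:
                wl = np.average([g.left_mean for g in group], axis=0,
                                weights=[g.n_left for g in group])
                wr = np.average([g.right_mean for g in group], axis=0,
                                weights=[g.n_right for g in group])
                si = symmetry_index(pearson_r(wl, wr))
            rows.append({"participant_id": pid, "condition": condition,
                         "si": si, "n_trials": len(group), "flag": ""})
    return pd.DataFrame(rows)
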