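"""Directory-level pipeline stages: simulate -> process -> analyze."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io as gio
from . import simulate as gsim
from . import speed as gspeed
from .config import PipelineConfig
from .report import analysis_report
from .symmetry import PipelineStageError, aggregate_si, compute_trial_si

log = logging.getLogger(__name__)


def simulate_to_dir(design: gsim.CohortDesign, seed: int, out_dir,
                    write_ground_truth: bool = True) -> Path:
    """Materialize a simulated cohort as trace CSVs plus participant/trial tables."""
    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    if write_ground_truth:
        (out / "ground_truth").mkdir(exist_ok=True)
    participants, trials = gsim.simulate_cohort(design, seed)
    pd.DataFrame([vars(p) for p in participants]).to_csv(
        out / "participants.csv", index=False)
    rows = []
    for tr in trials:
        fname = f"P{tr.participant_id}_{tr.condition}_{tr.trial}.csv"
        trace, gt = gsim.trial_trace(tr)
        gio.write_trace_csv(trace, out / "traces" / fname)
        if write_ground_truth:
            gio.write_ground_truth_json(gt, out / "ground_truth" / (fname[:-4] + ".json"))
        rows.append({"participant_id": tr.participant_id, "group": tr.group,
                     "condition": tr.condition, "trial": tr.trial,
                     "path_m": tr.path_m, "duration_s": tr.duration_s,
                     "file": f"traces/{fname}"})
    trials_df = pd.DataFrame(rows)
    trials_df.to_csv(out / "trials.csv", index=False)
    gio.write_manifest(out / "manifest.json", {"seed": seed}, [out / "trials.csv"],
                       {"simulate": {"n_participants": len(participants),
                                     "n_trials": len(trials)}})
    return out


def process_directory(in_dir, out_dir, config: PipelineConfig | None = None) -> Path:
    """Compute per-trial SI and speed tables from a simulated/recorded cohort dir."""
    cfg = config or PipelineConfig()
    in_path, out = Path(in_dir), Path(out_dir)
    if not in_path.exists():
        raise FileNotFoundError(f"input directory {in_path} does not exist")
    out.mkdir(parents=True, exist_ok=True)
    trials = pd.read_csv(in_path / "trials.csv")
    participants = pd.read_csv(in_path / "participants.csv")
    si_rows, qc = [], {"errors": []}
    for _, row in trials.iterrows():
        trace = gio.read_trace_csv(in_path / row["file"])
        try:
            res = compute_trial_si(trace, cfg, participant_id=row["participant_id"],
                                   condition=row["condition"], trial=int(row["trial"]))
        except PipelineStageError as exc:
            log.error("trial %s failed: %s", row["file"], exc)
            qc["errors"].append({"file": row["file"], "error": str(exc)})
            continue
        si_rows.append({"participant_id": row["participant_id"],
                        "group": row["group"], "condition": row["condition"],
                        "trial": int(row["trial"]), "r": res.r, "si": res.si,
                        "n_left": res.n_left, "n_right": res.n_right,
                        "qc_flags": "low-cycles" if res.qc.get("low_cycle_count") else "",
                        "observed_speed": gspeed.mean_speed(row["duration_s"],
                                                            row["path_m"])})
    si_df = pd.DataFrame(si_rows)
    si_df.to_csv(out / "si_results.csv", index=False)

    speed_tbl = (si_df.groupby(["participant_id", "condition"], as_index=False)
                 .agg(observed_speed=("observed_speed", "mean"))
                 .merge(participants[["participant_id", "group", "weight_kg",
                                      "height_cm"]], on="participant_id"))
    speed_df = gspeed.normalize_cohort_speeds(speed_tbl, scope=cfg.regression_scope)
    speed_df.to_csv(out / "speed_results.csv", index=False)
    gio.write_manifest(out / "manifest.json", cfg.to_dict(),
                       [in_path / "trials.csv"],
                       {"process": {"n_trials_ok": len(si_rows),
                                    "n_trials_failed": len(qc["errors"])}})
    return out


def build_cohort_table(si_results: pd.DataFrame, speed_results: pd.DataFrame,
                       aggregation: str = "mean-of-trials") -> pd.DataFrame:
    """Join aggregated SI and normalized speed into the long cohort table."""
    agg = (si_results.groupby(["participant_id", "group", "condition"], as_index=False)
           .agg(si=("si", "mean")))
    table = agg.merge(speed_results[["participant_id", "condition",
                                     "observed_speed", "normalized_speed"]],
                      on=["participant_id", "condition"], how="left")
    return table


def analyze_directory(in_dir, out_dir, config: PipelineConfig | None = None) -> dict:
    cfg = config or PipelineConfig()
    in_path = Path(in_dir)
    si = pd.read_csv(in_path / "si_results.csv")
    speed = pd.read_csv(in_path / "speed_results.csv")
    table = build_cohort_table(si, speed, aggregation=cfg.aggregation)
    results = analysis_report(table, out_dir, alpha=cfg.alpha)
    table.to_csv(Path(out_dir) / "cohort_table.csv", index=False)
    return results


def run_pipeline(design: gsim.CohortDesign, seed: int, work_dir,
                 config: PipelineConfig | None = None) -> dict:
    """simulate -> process -> analyze, returning the analysis results."""
    work = Path(work_dir)
    sim_dir = simulate_to_dir(design, seed, work / "input")
    proc_dir = process_directory(sim_dir, work / "processed", config)
    return analyze_directory(proc_dir, work / "report", config)
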