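"""Stage orchestration: simulate -> preprocess -> detect -> metrics ->
reliability, with tidy CSV outputs and a machine-readable JSON report.

Each stage reads the previous stage's outputs from the working directory,
so stages can be re-run individually. All randomness derives from the
config seed; re-running with an identical config reproduces identical
outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burst_detect import DetectionConfig, extract_bursts
from .data_model import (
    read_continuous_recording,
    read_trial_table,
    write_burst_table,
    read_burst_table,
    write_json_report,
    write_summary,
)
from .metrics import (
    inhibition_functions,
    participant_summary,
    peak_latency_variability,
    single_trial_prepare,
    ssd_profiles,
)
from .preprocess import PreprocessConfig, preprocess_participant
from .reliability import burst_metric_by_participant, split_half, titration
from .simulate import EmgConfig, SimConfig, make_fixture

log = logging.getLogger("premg")

STAGE_ORDER = ["simulate", "preprocess", "detect", "metrics", "reliability"]

#: reliability is estimated for these prEMG per-trial measures
RELIABILITY_METRICS = {
    "onset_go": "prEMG onset latency",
    "peak_stop": "prEMG peak latency",
    "peak_amp": "prEMG peak amplitude",
    "auc": "prEMG AUC",
}


def _dataclass_from(cls, mapping: dict | None):
    mapping = mapping or {}
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def default_config() -> dict:
    """The shipped defaults, serializable to YAML (all numeric values equal
    the study's parameters)."""
    return {
        "seed": 0,
        "sim": dataclasses.asdict(SimConfig()),
        "emg": {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(EmgConfig()).items()},
        "preprocess": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(PreprocessConfig()).items()},
        "detect": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(DetectionConfig()).items()},
        "metrics": {"staircase_step": 50.0, "span": 3},
        "reliability": {"n_perm": 10000, "titration": False, "titration_reps": 1000},
        "io": {"format": "brainvision", "event_codes": {"go": "go", "stop": "stop"}},
    }


def _tupled(mapping: dict, keys: tuple) -> dict:
    out = dict(mapping)
    for k in keys:
        if k in out and isinstance(out[k], list):
            out[k] = tuple(out[k])
    return out


def parse_configs(cfg: dict):
    sim = _dataclass_from(SimConfig, cfg.get("sim"))
    if "seed" in cfg:
        sim = dataclasses.replace(sim, seed=int(cfg["seed"]))
    emg = _dataclass_from(EmgConfig, _tupled(cfg.get("emg") or {}, ("carrier_band",)))
    pre = _dataclass_from(
        PreprocessConfig,
        _tupled(cfg.get("preprocess") or {}, ("band", "epoch_window", "baseline_window")),
    )
    det = _dataclass_from(
        DetectionConfig, _tupled(cfg.get("detect") or {}, ("search_window",))
    )
    return sim, emg, pre, det


def _participants(out_dir: Path) -> list:
    return sorted(p.name.replace("_events.tsv", "")
                  for p in out_dir.glob("*_events.tsv"))


def run(config: dict, stages: list | None = None, out_dir: str | Path = "premg_out") -> dict:
    """Execute the requested stages in order and return the JSON report."""
    if stages is None:
        stages = list(STAGE_ORDER)
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGE_ORDER if s in stages]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim_cfg, emg_cfg, pre_cfg, det_cfg = parse_configs(config)
    io_cfg = config.get("io") or {}
    fmt = io_cfg.get("format", "brainvision")
    hand_map = io_cfg.get("hand_map") or {"EMG_left": "left", "EMG_right": "right"}
    report: dict = {
        "version": __version__,
        "seed": sim_cfg.seed,
        "stages": stages,
        "parameters": {
            "sim": dataclasses.asdict(sim_cfg),
            "emg": dataclasses.asdict(emg_cfg),
            "preprocess": dataclasses.asdict(pre_cfg),
            "detect": dataclasses.asdict(det_cfg),
        },
    }

    if "simulate" in stages:
        log.info("simulate: %d participants", sim_cfg.n_participants)
        manifest = make_fixture(sim_cfg, emg_cfg, out_dir, fmt)
        report["simulate"] = {"participants": sorted(manifest)}

    pids = _participants(out_dir)
    if not pids and set(stages) - {"simulate"}:
        raise FileNotFoundError(f"no trial tables (*_events.tsv) found in {out_dir}")

    if "preprocess" in stages or "detect" in stages:
        rejections = {}
        n_bursts = {}
        for pid in pids:
            trials = read_trial_table(out_dir / f"{pid}_events.tsv")
            ext = ".vhdr" if fmt == "brainvision" else ".tsv"
            rec_path = out_dir / f"{pid}_emg{ext}"
            if not rec_path.exists():
                raise FileNotFoundError(f"recording absent for {pid}: {rec_path}")
            rec = read_continuous_recording(rec_path, fmt, hand_map=hand_map)
            epochs = preprocess_participant(rec, trials, pre_cfg)
            rejections[pid] = dict(epochs.rejected)
            if "detect" in stages:
                bursts = extract_bursts(epochs, trials, det_cfg)
                bursts.insert(0, "participant", pid)
                write_burst_table(bursts, out_dir / f"{pid}_bursts.csv")
                n_bursts[pid] = int(bursts["detected"].sum())
            log.info("preprocess %s: %d trials, %d rejected",
                     pid, len(trials), len(epochs.rejected))
        report["preprocess"] = {
            "rejected": {p: len(r) for p, r in rejections.items()},
            "rejection_rate": float(
                np.mean([len(r) for r in rejections.values()])
                / max(len(read_trial_table(out_dir / f"{pids[0]}_events.tsv")), 1)
            ) if pids else 0.0,
        }
        if "detect" in stages:
            report["detect"] = {"bursts_detected": n_bursts}

    if "metrics" in stages:
        summaries, inhib, profiles, singles, all_bursts = [], [], [], [], []
        for pid in pids:
            trials = read_trial_table(out_dir / f"{pid}_events.tsv")
            bpath = out_dir / f"{pid}_bursts.csv"
            if not bpath.exists():
                raise FileNotFoundError(f"burst table absent for {pid}: {bpath}")
            bursts = read_burst_table(bpath)
            all_bursts.append(bursts)
            summaries.append(participant_summary(pid, trials, bursts))
            for table, sink in ((inhibition_functions(trials, bursts), inhib),
                                (ssd_profiles(trials, bursts), profiles),
                                (single_trial_prepare(bursts, trials), singles)):
                if "participant" not in table.columns:
                    table.insert(0, "participant", pid)
                sink.append(table)
        write_summary(summaries, out_dir / "participant_summary.csv")
        pd.concat(inhib, ignore_index=True).to_csv(
            out_dir / "inhibition_functions.csv", index=False, na_rep="")
        pd.concat(profiles, ignore_index=True).to_csv(
            out_dir / "ssd_profiles.csv", index=False, na_rep="")
        pd.concat(singles, ignore_index=True).to_csv(
            out_dir / "single_trial.csv", index=False, na_rep="")
        pooled = pd.concat(all_bursts, ignore_index=True)
        variability = peak_latency_variability(pooled)
        variability.to_csv(out_dir / "variability.csv", index=False, na_rep="")
        srows = pd.DataFrame([s.to_row() for s in summaries])
        report["metrics"] = {
            "n_participants": len(pids),
            "mean_stop_accuracy_pct": float(srows["beh_stop_accuracy_pct"].mean()),
            "mean_ssd": float(srows["beh_mean_ssd"].mean()),
            "mean_ssrt": float(srows["beh_ssrt"].mean()),
            "mean_premg_detected_pct": float(srows["emg_premg_detected_pct"].mean()),
            "mean_premg_peak_single_trial": float(
                srows["emg_premg_peak_single_trial"].mean()),
            "mean_motor_time_go": float(srows["emg_go_motor_time"].mean()),
        }

    if "reliability" in stages:
        rel_cfg = config.get("reliability") or {}
        n_perm = int(rel_cfg.get("n_perm", 10000))
        bursts_files = sorted(out_dir.glob("*_bursts.csv"))
        if not bursts_files:
            raise FileNotFoundError(f"no burst tables in {out_dir}")
        pooled = pd.concat([read_burst_table(p) for p in bursts_files],
                           ignore_index=True)
        rel_rows = []
        rel_report = {}
        for col, label in RELIABILITY_METRICS.items():
            values = burst_metric_by_participant(pooled, col)
            try:
                est = split_half(values, n_perm=n_perm, seed=sim_cfg.seed, metric=label)
            except ValueError as err:
                log.warning("reliability %s skipped: %s", label, err)
                continue
            rel_rows.append({
                "metric": label, "r_mean": est.r_mean, "r_sd": est.r_sd,
                "ci_low": est.ci[0], "ci_high": est.ci[1],
                "n_perm": est.n_perm, "n_participants": est.n_participants,
                "n_trials_used": est.n_trials_used,
            })
            rel_report[col] = est.r_mean
        pd.DataFrame(rel_rows).to_csv(out_dir / "reliability.csv", index=False)
        if rel_cfg.get("titration", False):
            values = burst_metric_by_participant(pooled, "peak_stop")
            curve = titration(values, n_reps=int(rel_cfg.get("titration_reps", 1000)),
                              seed=sim_cfg.seed, metric="prEMG peak latency")
            curve.to_csv(out_dir / "titration.csv", index=False)
            rel_report["titration_rows"] = len(curve)
        report["reliability"] = rel_report

    write_json_report(report, out_dir / "report.json")
    return report
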