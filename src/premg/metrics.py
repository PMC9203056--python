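"""Behavioral and EMG summary metrics for the stop signal task.

Single-participant functions take that participant's trial table and burst
table; cohort aggregation (group means over participants) is done by the
pipeline via plain concatenation, so that each participant contributes one
value regardless of trial counts. Where a metric is defined per hand, the
reported value is the mean of the per-hand values (explicit mean of hand
means, so asymmetric trial counts do not silently reweight).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import EpochSet, ParticipantSummary

__all__ = [
    "SsrtResult",
    "behavioral_summary",
    "ssrt_integration",
    "premg_peak_latency",
    "modal_ssd",
    "centered_ssd_steps",
    "inhibition_functions",
    "partition_go_distribution",
    "ssd_profiles",
    "single_trial_prepare",
    "peak_latency_variability",
    "hand_averaged",
    "participant_summary",
]


@dataclass(frozen=True)
class SsrtResult:
    ssrt: float
    p_respond: float
    mean_ssd: float
    valid: bool


def ssrt_integration(trials: pd.DataFrame) -> SsrtResult:
    """Integration-method SSRT with go-omission replacement.

    The go-RT vector includes choice-error RTs; every omission is replaced
    by the participant's maximum observed go RT. With p = P(response|stop),
    the SSRT is the p-th quantile of the ascending go-RT vector (rank
    ``ceil(p*n)``, 1-based) minus the mean SSD over stop trials. p = 0 or 1
    leaves the estimate undefined (``valid=False``).
    """
    go = trials[trials["trial_type"] == "go"]
    stop = trials[trials["trial_type"] == "stop"]
    if len(stop) == 0:
        raise ValueError("no stop trials")
    observed = go["rt"].dropna().to_numpy(float)
    if observed.size == 0:
        raise ValueError("no go responses")
    n_omit = int(go["rt"].isna().sum())
    vec = np.sort(np.concatenate([observed, np.full(n_omit, observed.max())]))
    p = float((stop["outcome"] == "stop_fail").mean())
    mean_ssd = float(stop["ssd"].mean())
    if p <= 0.0 or p >= 1.0:
        return SsrtResult(float("nan"), p, mean_ssd, False)
    rank = math.ceil(p * len(vec))
    return SsrtResult(float(vec[rank - 1]) - mean_ssd, p, mean_ssd, True)


def behavioral_summary(trials: pd.DataFrame) -> dict:
    """Go accuracy/error/omission %, mean correct go RT, mean unsuccessful-
    stop RT, mean SSD, stop accuracy %, and the integration SSRT."""
    go = trials[trials["trial_type"] == "go"]
    stop = trials[trials["trial_type"] == "stop"]
    if len(stop) == 0:
        raise ValueError("no stop trials")
    n_go = len(go)
    res = ssrt_integration(trials)
    return {
        "go_accuracy_pct": 100.0 * (go["outcome"] == "go_correct").sum() / n_go,
        "go_error_pct": 100.0 * (go["outcome"] == "go_error").sum() / n_go,
        "go_omission_pct": 100.0 * (go["outcome"] == "go_omission").sum() / n_go,
        "go_rt": float(go.loc[go["outcome"] == "go_correct", "rt"].mean()),
        "ustop_rt": float(stop.loc[stop["outcome"] == "stop_fail", "rt"].mean()),
        "mean_ssd": res.mean_ssd,
        "stop_accuracy_pct": 100.0 * (stop["outcome"] == "stop_success").sum() / len(stop),
        "ssrt": res.ssrt,
        "p_respond_stop": res.p_respond,
    }


# ---------------------------------------------------------------------------
# prEMG peak-latency estimators
# ---------------------------------------------------------------------------

def modal_ssd(ssds: pd.Series | np.ndarray) -> float:
    """Most frequent SSD; ties resolved to the lowest SSD."""
    vals, counts = np.unique(np.asarray(ssds, float), return_counts=True)
    return float(vals[np.argmax(counts)])  # argmax -> first (= lowest) on ties


def premg_peak_latency(bursts: pd.DataFrame, trials: pd.DataFrame,
                       method: str = "single_trial",
                       epochs: EpochSet | None = None) -> float:
    """Participant-level prEMG peak latency (ms after the stop signal).

    single_trial
        Mean of the per-trial stop-locked peaks over prEMG trials.
    average_waveform
        Peak of the point-wise mean of the stop-locked envelopes of all
        prEMG trials (requires ``epochs``); SSD shifts are rounded to whole
        samples and the peak is searched from the stop signal onward.
    mode_ssd
        Mean per-trial stop-locked peak over prEMG trials at the
        participant's modal SSD (mode over all stop trials, ties -> lowest);
        NaN when no prEMG trial sits at the modal SSD.

    Returns NaN when the participant has no prEMG trials.
    """
    pr = bursts[bursts["emg_class"] == "premg"]
    if len(pr) == 0:
        return float("nan")
    if method == "single_trial":
        return float(pr["peak_stop"].mean())
    if method == "mode_ssd":
        stop = trials[trials["trial_type"] == "stop"]
        mode = modal_ssd(stop["ssd"])
        ssd_by_id = trials.set_index("trial_id")["ssd"]
        at_mode = pr[ssd_by_id.loc[pr["trial_id"]].to_numpy() == mode]
        return float(at_mode["peak_stop"].mean()) if len(at_mode) else float("nan")
    if method == "average_waveform":
        if epochs is None:
            raise ValueError("average_waveform needs the z-scored epochs")
        epochs.require_stage("zscored")
        ssd_by_id = trials.set_index("trial_id")["ssd"]
        row_of = {tid: i for i, tid in enumerate(epochs.trial_ids)}
        n = len(epochs.time)
        acc = np.zeros(n)
        cnt = np.zeros(n)
        for tid in pr["trial_id"]:
            shift = int(round(ssd_by_id.loc[tid] / 1000.0 * epochs.rate))
            trace = epochs.data[row_of[tid]]
            # stop-locked trace: sample k corresponds to time[k] - ssd
            acc[: n - shift] += trace[shift:]
            cnt[: n - shift] += 1
        with np.errstate(invalid="ignore"):
            mean_wave = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
        stop_time = epochs.time  # now stop-locked
        valid = (stop_time >= 0) & (cnt > 0)
        if not valid.any():
            return float("nan")
        seg = np.where(valid, mean_wave, -np.inf)
        return float(stop_time[int(np.argmax(seg))] * 1000.0)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# inhibition functions and SSD profiles
# ---------------------------------------------------------------------------

def centered_ssd_steps(trials: pd.DataFrame, step: float = 50.0, span: int = 3) -> pd.Series:
    """Per stop trial: SSD recoded in staircase steps around the modal SSD
    (mode = 0); trials beyond ±span steps get NaN."""
    stop = trials[trials["trial_type"] == "stop"]
    mode = modal_ssd(stop["ssd"])
    steps = (stop["ssd"] - mode) / step
    steps = steps.round().astype(float)
    steps[np.abs(steps) > span] = np.nan
    return steps


def inhibition_functions(trials: pd.DataFrame, bursts: pd.DataFrame,
                         step: float = 50.0, span: int = 3) -> pd.DataFrame:
    """Empirical p(button press | stop) and p(EMG | stop) per mode-centered
    SSD step for one participant.

    p(EMG|stop) counts failed stops plus successful stops with prEMG, so it
    dominates p(press|stop) by set inclusion.
    """
    stop = trials[trials["trial_type"] == "stop"].copy()
    stop["step"] = centered_ssd_steps(trials, step, span)
    det = bursts.set_index("trial_id")["emg_class"]
    stop["premg"] = [
        det.get(tid) == "premg" for tid in stop["trial_id"]
    ]
    stop = stop.dropna(subset=["step"])
    rows = []
    for s, grp in stop.groupby("step"):
        pressed = (grp["outcome"] == "stop_fail")
        rows.append({
            "step": s,
            "n_trials": len(grp),
            "p_press": float(pressed.mean()),
            "p_emg": float((pressed | grp["premg"]).mean()),
        })
    return pd.DataFrame(rows).sort_values("step").reset_index(drop=True)


def ssd_profiles(trials: pd.DataFrame, bursts: pd.DataFrame,
                 step: float = 50.0, span: int = 3) -> pd.DataFrame:
    """prEMG probability, go-locked onset, stop-locked peak and peak
    amplitude per mode-centered SSD step (one participant; cells without
    prEMG trials stay NaN)."""
    stop = trials[trials["trial_type"] == "stop"].copy()
    stop["step"] = centered_ssd_steps(trials, step, span)
    stop = stop.dropna(subset=["step"])
    pr = bursts[bursts["emg_class"] == "premg"].set_index("trial_id")
    rows = []
    for s, grp in stop.groupby("step"):
        ids = [tid for tid in grp["trial_id"] if tid in pr.index]
        sub = pr.loc[ids]
        rows.append({
            "step": s,
            "n_stop": len(grp),
            "premg_probability": len(ids) / len(grp),
            "onset_go": float(sub["onset_go"].mean()) if len(ids) else float("nan"),
            "peak_stop": float(sub["peak_stop"].mean()) if len(ids) else float("nan"),
            "peak_amp": float(sub["peak_amp"].mean()) if len(ids) else float("nan"),
        })
    return pd.DataFrame(rows).sort_values("step").reset_index(drop=True)


# ---------------------------------------------------------------------------
# context-independence partitions
# ---------------------------------------------------------------------------

def _partition(values: np.ndarray, p_press: float, p_emg: float):
    """Tile the sorted go distribution into fast/medium/slow at the ranks
    ceil(p_press*n) and ceil(p_emg*n)."""
    v = np.sort(np.asarray(values, float))
    n = len(v)
    n_fast = min(math.ceil(p_press * n), n)
    n_med = min(max(math.ceil(p_emg * n), n_fast), n)
    return v[:n_fast], v[n_fast:n_med], v[n_med:]


def partition_go_distribution(trials: pd.DataFrame, bursts: pd.DataFrame,
                              p_press: float, p_emg: float,
                              level: str = "rt",
                              n_subsamples: int = 0,
                              rng: np.random.Generator | None = None) -> dict:
    """Race-model partition test on the go distribution of one participant.

    The go distribution (responded-go RTs, or go-trial EMG onsets when
    ``level="emg_onset"``) is split at the percentiles p(press|stop) and
    p(EMG|stop): the fast portion should match unsuccessful-stop trials, the
    medium portion should match prEMG trials. Returns per-portion means and
    medians plus the comparison values (usRT / us-EMG onset / prEMG onset).

    With ``n_subsamples > 0``, fast and medium portions are re-drawn as
    size-matched random subsets (matching the unsuccessful-stop and prEMG
    trial counts) and the fraction of draws in which the empirical ordering
    (comparison mean below the portion mean) is preserved is reported.
    """
    if not 0.0 <= p_press <= p_emg <= 1.0:
        raise ValueError("need 0 <= p_press <= p_emg <= 1")
    stop = trials[trials["trial_type"] == "stop"]
    cls = bursts.set_index("trial_id")
    if level == "rt":
        values = trials.loc[(trials["trial_type"] == "go") & trials["rt"].notna(), "rt"].to_numpy(float)
        us_comp = stop.loc[stop["outcome"] == "stop_fail", "rt"].to_numpy(float)
    elif level == "emg_onset":
        go_emg = cls[cls["emg_class"] == "go_emg"]
        values = go_emg["onset_go"].dropna().to_numpy(float)
        us_comp = cls.loc[cls["emg_class"] == "ustop_emg", "onset_go"].dropna().to_numpy(float)
    else:
        raise ValueError(f"unknown level {level!r}")
    if len(values) == 0:
        raise ValueError("empty go distribution")
    premg_onsets = cls.loc[cls["emg_class"] == "premg", "onset_go"].dropna().to_numpy(float)
    fast, med, slow = _partition(values, p_press, p_emg)
    out = {
        "level": level,
        "n": len(values),
        "counts": (len(fast), len(med), len(slow)),
        "fast_mean": float(fast.mean()) if len(fast) else float("nan"),
        "fast_median": float(np.median(fast)) if len(fast) else float("nan"),
        "medium_mean": float(med.mean()) if len(med) else float("nan"),
        "medium_median": float(np.median(med)) if len(med) else float("nan"),
        "slow_mean": float(slow.mean()) if len(slow) else float("nan"),
        "slow_median": float(np.median(slow)) if len(slow) else float("nan"),
        "us_mean": float(us_comp.mean()) if len(us_comp) else float("nan"),
        "us_median": float(np.median(us_comp)) if len(us_comp) else float("nan"),
        "premg_onset_mean": float(premg_onsets.mean()) if len(premg_onsets) else float("nan"),
    }
    if n_subsamples > 0:
        rng = np.random.default_rng() if rng is None else rng
        n_us = min(len(us_comp), len(fast))
        n_pr = min(len(premg_onsets), len(med))
        keep_fast = 0
        keep_med = 0
        for _ in range(n_subsamples):
            if n_us and len(fast):
                sub = rng.choice(fast, size=n_us, replace=False)
                keep_fast += sub.mean() >= out["us_mean"]
            if n_pr and len(med):
                sub = rng.choice(med, size=n_pr, replace=False)
                keep_med += sub.mean() >= out["premg_onset_mean"]
        out["frac_fast_ge_us"] = keep_fast / n_subsamples if n_us else float("nan")
        out["frac_medium_ge_premg"] = keep_med / n_subsamples if n_pr else float("nan")
    return out


# ---------------------------------------------------------------------------
# single-trial preparation and variability
# ---------------------------------------------------------------------------

def single_trial_prepare(bursts: pd.DataFrame, trials: pd.DataFrame,
                         min_trials: int = 3) -> pd.DataFrame:
    """Clean and transform one participant's prEMG trials for single-trial
    analyses.

    Steps: drop trials whose peak precedes the stop signal; drop trials
    whose go-locked onset or stop-locked peak lies outside
    [Q1 - 2 IQR, Q3 + 2 IQR] of this participant's values
    (linear-interpolation quartiles); residualize onset on SSD by ordinary
    least squares (``onset_resid`` column); natural-log-transform the AUC.
    With fewer than ``min_trials`` surviving prEMG trials the
    residualization is skipped and ``resid_skipped`` is True for all rows.
    """
    pr = bursts[bursts["emg_class"] == "premg"].copy()
    ssd_by_id = trials.set_index("trial_id")["ssd"]
    pr["ssd"] = ssd_by_id.loc[pr["trial_id"]].to_numpy()
    pr = pr[~pr["pre_stop_peak"]]
    for col in ("onset_go", "peak_stop"):
        if len(pr) == 0:
            break
        q1, q3 = np.percentile(pr[col], [25, 75])
        iqr = q3 - q1
        pr = pr[(pr[col] >= q1 - 2 * iqr) & (pr[col] <= q3 + 2 * iqr)]
    pr = pr.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        pr["log_auc"] = np.where(pr["auc"] > 0, np.log(pr["auc"]), np.nan)
    if len(pr) >= min_trials:
        if np.ptp(pr["ssd"].to_numpy()) > 0:
            slope, intercept = np.polyfit(pr["ssd"], pr["onset_go"], 1)
            pr["onset_resid"] = pr["onset_go"] - (slope * pr["ssd"] + intercept)
        else:  # constant SSD: the regression degenerates to the mean
            pr["onset_resid"] = pr["onset_go"] - pr["onset_go"].mean()
        pr["resid_skipped"] = False
    else:
        pr["onset_resid"] = np.nan
        pr["resid_skipped"] = True
    return pr.reset_index(drop=True)


def peak_latency_variability(bursts_by_participant: pd.DataFrame,
                             min_trials: int = 2) -> pd.DataFrame:
    """Per-participant sd of stop-locked prEMG peak latencies (sample sd,
    n-1 divisor) with an upper-tail outlier flag.

    Expects a burst table with a ``participant`` column. Participants with
    fewer than ``min_trials`` prEMG trials get NaN. A participant is flagged
    when their sd exceeds Q3 + 2 IQR of the group sd distribution.
    """
    pr = bursts_by_participant[bursts_by_participant["emg_class"] == "premg"]
    rows = []
    for pid, grp in pr.groupby("participant"):
        peaks = grp["peak_stop"].dropna()
        sd = float(peaks.std(ddof=1)) if len(peaks) >= min_trials else float("nan")
        rows.append({"participant": pid, "n_premg": len(peaks), "peak_sd": sd})
    out = pd.DataFrame(rows, columns=["participant", "n_premg", "peak_sd"])
    finite = out["peak_sd"].dropna()
    if len(finite) >= 4:
        q1, q3 = np.percentile(finite, [25, 75])
        cut = q3 + 2 * (q3 - q1)
        out["outlier"] = out["peak_sd"] > cut
    else:
        out["outlier"] = False
    return out


# ---------------------------------------------------------------------------
# participant summary
# ---------------------------------------------------------------------------

def hand_averaged(values: pd.Series, hands: pd.Series) -> float:
    """Mean of per-hand means (the documented averaging): each hand with
    data contributes equally, so asymmetric trial counts do not reweight."""
    df = pd.DataFrame({"v": values, "h": hands}).dropna(subset=["v"])
    if len(df) == 0:
        return float("nan")
    return float(df.groupby("h")["v"].mean().mean())


def participant_summary(participant: str, trials: pd.DataFrame,
                        bursts: pd.DataFrame,
                        epochs: EpochSet | None = None) -> ParticipantSummary:
    """Assemble the behavioral and EMG blocks for one participant.

    EMG latency/amplitude metrics are hand-averaged (mean of hand means).
    """
    beh = behavioral_summary(trials)
    hand_by_id = trials.set_index("trial_id")["required_hand"]
    b = bursts.copy()
    b["hand"] = hand_by_id.loc[b["trial_id"]].to_numpy()
    emg: dict = {}
    class_of = {"go_emg": "go", "premg": "premg", "ustop_emg": "ustop"}
    denom = {
        "go": (trials["trial_type"] == "go").sum(),
        "premg": (trials["outcome"] == "stop_success").sum(),
        "ustop": (trials["outcome"] == "stop_fail").sum(),
    }
    for cls, name in class_of.items():
        sub = b[b["emg_class"] == cls]
        emg[f"{name}_count"] = float(len(sub))
        emg[f"{name}_detected_pct"] = (
            100.0 * len(sub) / denom[name] if denom[name] else float("nan")
        )
        for col in ("onset_go", "peak_go", "peak_amp", "motor_time", "rise_time", "auc"):
            emg[f"{name}_{col}"] = hand_averaged(sub[col], sub["hand"])
        if cls != "go_emg":
            emg[f"{name}_peak_stop"] = hand_averaged(sub["peak_stop"], sub["hand"])
    for method in ("single_trial", "average_waveform", "mode_ssd"):
        try:
            emg[f"premg_peak_{method}"] = premg_peak_latency(
                bursts, trials, method=method, epochs=epochs
            )
        except ValueError:
            emg[f"premg_peak_{method}"] = float("nan")
    pr_peaks = b.loc[b["emg_class"] == "premg", "peak_stop"].dropna()
    emg["premg_peak_sd"] = float(pr_peaks.std(ddof=1)) if len(pr_peaks) >= 2 else float("nan")
    return ParticipantSummary(participant=participant, behavioral=beh, emg=emg)
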