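"""Threshold-based EMG burst detection on z-scored envelope epochs.

A burst is detected in a trial when any envelope sample inside the search
window exceeds the z threshold. The peak is the global maximum of the
windowed trace (earliest index wins on ties); the onset is found by walking
backwards from the peak until a sufficiently long sub-threshold run, the
onset being the first supra-threshold sample after that run. Stop-trial peak
latencies are re-expressed relative to the stop signal by subtracting the
SSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import BURST_COLUMNS, EpochSet

__all__ = [
    "DetectionConfig",
    "detect_peak",
    "trace_onset",
    "stop_lock",
    "classify_trial_emg",
    "extract_bursts",
]


@dataclass(frozen=True)
class DetectionConfig:
    """threshold in z units; onset_run_ms is the length of the sub-threshold
    run that terminates the backward onset trace; search_window in seconds
    post-go (the default excludes the baseline so that pre-go noise cannot
    trigger detection)."""

    threshold: float = 1.2
    onset_run_ms: float = 8.0
    search_window: tuple = (0.0, 1.6)

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.onset_run_ms <= 0:
            raise ValueError("onset_run_ms must be positive")

    def run_samples(self, rate: float) -> int:
        n = self.onset_run_ms * rate / 1000.0
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError(
                f"onset_run_ms ({self.onset_run_ms}) is not a positive multiple "
                f"of the sample period at {rate} Hz"
            )
        return int(round(n))


def _window_indices(time: np.ndarray, window: tuple) -> np.ndarray:
    idx = np.nonzero((time >= window[0] - 1e-12) & (time <= window[1] + 1e-12))[0]
    if idx.size == 0:
        raise ValueError("empty search window")
    return idx


def detect_peak(trace: np.ndarray, time: np.ndarray, config: DetectionConfig = DetectionConfig()):
    """Return ``(detected, peak_index, peak_amp)`` for one epoch.

    ``detected`` is True iff any sample in the search window strictly
    exceeds the threshold; ``peak_index`` indexes the full epoch.
    """
    idx = _window_indices(time, config.search_window)
    seg = trace[idx]
    detected = bool((seg > config.threshold).any())
    peak_local = int(np.argmax(seg))  # argmax -> earliest index on ties
    peak_index = int(idx[peak_local])
    return detected, peak_index, float(trace[peak_index])


def trace_onset(trace: np.ndarray, time: np.ndarray, peak_index: int, rate: float,
                config: DetectionConfig = DetectionConfig()):
    """Walk backwards from the peak to the burst onset.

    Returns ``(onset_index, at_window_start)``. The trace stops at the first
    run of ``onset_run_ms`` worth of consecutive sub-threshold samples; the
    onset is the first supra-threshold sample following that run (the
    earliest sample of the detected burst). If no such run exists before the
    search-window start, the onset falls back to the window start with
    ``at_window_start=True``.
    """
    if not (0 <= peak_index < len(trace)):
        raise ValueError("peak index outside epoch")
    idx = _window_indices(time, config.search_window)
    start = int(idx[0])
    run_needed = config.run_samples(rate)
    thr = config.threshold
    count = 0
    last_supra = peak_index
    for i in range(peak_index, start - 1, -1):
        if trace[i] < thr:
            count += 1
            if count >= run_needed:
                return last_supra, False
        else:
            count = 0
            last_supra = i
    return start, True


def stop_lock(peak_go: float, ssd: float) -> float:
    """Stop-locked peak latency in ms: peak_go - ssd (may be negative)."""
    if ssd is None or (isinstance(ssd, float) and np.isnan(ssd)):
        raise ValueError("SSD absent; cannot stop-lock a latency")
    return peak_go - ssd


def classify_trial_emg(outcome: str, detected: bool) -> str:
    """EMG class of a trial: go trials with a burst -> go_emg, failed stops
    with a burst -> ustop_emg, successful stops with a burst -> premg,
    otherwise none."""
    if not detected:
        return "none"
    if outcome in ("go_correct", "go_error", "go_omission"):
        return "go_emg"
    if outcome == "stop_fail":
        return "ustop_emg"
    if outcome == "stop_success":
        return "premg"
    raise ValueError(f"unknown outcome {outcome!r}")


def extract_bursts(epochs: EpochSet, trials: pd.DataFrame,
                   config: DetectionConfig = DetectionConfig()) -> pd.DataFrame:
    """Detect bursts on every non-rejected trial and assemble the burst table.

    One row per non-rejected trial. Latencies are in ms: ``onset_go`` /
    ``peak_go`` are go-locked, ``peak_stop`` subtracts the SSD (stop trials
    only). ``motor_time = rt - onset_go`` (responded trials), ``rise_time =
    peak_go - onset_go`` and ``auc`` is the cumulative envelope amplitude
    from onset to peak (inclusive). Trials whose prEMG peak precedes the
    stop signal stay in the table flagged ``pre_stop_peak``; they are
    excluded later, in the single-trial preparation.
    """
    epochs.require_stage("zscored")
    if len(epochs.trial_ids) != len(trials):
        raise ValueError("epochs and trial table are misaligned")
    by_id = trials.set_index("trial_id")
    rows = []
    for i, tid in enumerate(epochs.trial_ids):
        if tid in epochs.rejected:
            continue
        trial = by_id.loc[tid]
        trace = epochs.data[i]
        detected, peak_idx, peak_amp = detect_peak(trace, epochs.time, config)
        row = {
            "trial_id": tid,
            "detected": detected,
            "onset_go": np.nan,
            "peak_go": np.nan,
            "peak_stop": np.nan,
            "peak_amp": np.nan,
            "motor_time": np.nan,
            "rise_time": np.nan,
            "auc": np.nan,
            "emg_class": classify_trial_emg(trial["outcome"], detected),
            "onset_at_window_start": False,
            "pre_stop_peak": False,
        }
        if detected:
            onset_idx, at_start = trace_onset(trace, epochs.time, peak_idx, epochs.rate, config)
            onset_go = epochs.time[onset_idx] * 1000.0
            peak_go = epochs.time[peak_idx] * 1000.0
            row.update(
                onset_go=onset_go,
                peak_go=peak_go,
                peak_amp=peak_amp,
                rise_time=peak_go - onset_go,
                auc=float(trace[onset_idx : peak_idx + 1].sum()),
                onset_at_window_start=at_start,
            )
            if trial["trial_type"] == "stop":
                row["peak_stop"] = stop_lock(peak_go, trial["ssd"])
                row["pre_stop_peak"] = bool(row["peak_stop"] < 0)
            if pd.notna(trial["rt"]):
                row["motor_time"] = trial["rt"] - onset_go
        rows.append(row)
    return pd.DataFrame(rows, columns=BURST_COLUMNS)
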