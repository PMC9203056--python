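"""Domain types and I/O for stop-signal-task EMG analyses.

Time conventions: continuous recordings and event/go onsets are in seconds on
the recording clock; latency-type quantities (SSD, RT, burst latencies, motor
and rise times) are in milliseconds. The conversion happens exactly once, at
epoching.

Missing values are serialized as empty fields, never as sentinel numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ContinuousRecording",
    "EpochSet",
    "ParticipantSummary",
    "STAGES",
    "TRIAL_COLUMNS",
    "derive_outcome",
    "read_continuous_recording",
    "read_trial_table",
    "write_trial_table",
    "read_burst_table",
    "write_burst_table",
    "write_summary",
    "read_summary",
]

#: processing stages of an EpochSet, in the only admissible order
STAGES = ("filtered", "rms", "baseline_normalized", "zscored")

TRIAL_COLUMNS = [
    "trial_id",
    "block",
    "trial_type",
    "go_onset",
    "ssd",
    "required_hand",
    "response_hand",
    "rt",
    "outcome",
]

#: BurstTable column order (one row per non-rejected trial)
BURST_COLUMNS = [
    "trial_id",
    "detected",
    "onset_go",
    "peak_go",
    "peak_stop",
    "peak_amp",
    "motor_time",
    "rise_time",
    "auc",
    "emg_class",
    "onset_at_window_start",
    "pre_stop_peak",
]


class StageError(RuntimeError):
    """Raised when a preprocessing operation is applied out of order."""


@dataclass
class ContinuousRecording:
    """Multichannel surface-EMG recording.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    rate : float
        Sampling frequency in Hz.
    channels : list of str
        Channel labels, one per row of ``samples``.
    hand_map : dict
        Channel label -> responding hand ("left"/"right"). Assignment is
        explicit configuration, never inferred from labels.
    events : list of (float, str)
        (time in seconds, event code) markers.
    meta : dict
        Free-form provenance record.
    """

    samples: np.ndarray
    rate: float
    channels: list
    hand_map: dict = field(default_factory=dict)
    events: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels x time) matrix")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError("one label per channel row required")
        if self.samples.shape[0] == 0:
            raise ValueError("recording has zero channels")
        dur = self.duration
        for t, _ in self.events:
            if not (0.0 <= t <= dur):
                raise ValueError(f"event at {t} s outside recording [0, {dur:.3f}]")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.samples.shape[1] / self.rate

    def channel_for_hand(self, hand: str) -> int:
        """Row index of the channel assigned to ``hand``; raises if unmapped."""
        for i, ch in enumerate(self.channels):
            if self.hand_map.get(ch) == hand:
                return i
        raise KeyError(f"no channel assigned to hand {hand!r}")


@dataclass
class EpochSet:
    """Trials x time matrix locked to go-signal onset.

    ``data[i]`` holds the epoch of trial ``trial_ids[i]``, taken from the
    channel of that trial's required hand. ``time`` is in seconds relative to
    the go signal and contains the sample at t = 0. ``rejected`` maps a
    trial's row to a rejection reason; rejected trials are carried along but
    produce no downstream metrics.
    """

    data: np.ndarray
    time: np.ndarray
    rate: float
    stage: str
    trial_ids: np.ndarray
    hands: np.ndarray
    blocks: np.ndarray
    rejected: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}")
        dt = np.diff(self.time)
        if len(dt) and not np.allclose(dt, 1.0 / self.rate, rtol=1e-6):
            raise ValueError("time axis must increase in steps of 1/rate")
        if self.data.shape != (len(self.trial_ids), len(self.time)):
            raise ValueError("data shape inconsistent with trial_ids/time")

    def require_stage(self, stage: str) -> None:
        if self.stage != stage:
            raise StageError(
                f"operation requires stage {stage!r}, epochs are at {self.stage!r}"
            )

    def advance(self, data: np.ndarray, stage: str) -> "EpochSet":
        """Return a copy at the next processing stage."""
        if STAGES.index(stage) != STAGES.index(self.stage) + 1:
            raise StageError(f"illegal stage transition {self.stage!r} -> {stage!r}")
        return EpochSet(
            data=data,
            time=self.time,
            rate=self.rate,
            stage=stage,
            trial_ids=self.trial_ids.copy(),
            hands=self.hands.copy(),
            blocks=self.blocks.copy(),
            rejected=dict(self.rejected),
        )

    def kept_mask(self) -> np.ndarray:
        return np.array([tid not in self.rejected for tid in self.trial_ids])


def derive_outcome(trial_type: str, required_hand: str, response_hand: str, rt) -> str:
    """Outcome label as a pure function of the raw trial fields.

    go trials: correct-hand response -> go_correct, wrong hand -> go_error,
    no response -> go_omission. stop trials: any response -> stop_fail,
    none -> stop_success.
    """
    responded = response_hand in ("left", "right")
    if responded and (rt is None or (isinstance(rt, float) and np.isnan(rt))):
        raise ValueError("response without RT")
    if trial_type == "go":
        if not responded:
            return "go_omission"
        return "go_correct" if response_hand == required_hand else "go_error"
    if trial_type == "stop":
        return "stop_fail" if responded else "stop_success"
    raise ValueError(f"unknown trial_type {trial_type!r}")


def validate_trial_table(df: pd.DataFrame, response_window: float = 1000.0) -> pd.DataFrame:
    """Validate a trial table and (re)derive the outcome column.

    Raises on a stop trial without SSD, or an RT without a response hand.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "outcome"]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    df = df.copy()
    df["response_hand"] = df["response_hand"].fillna("none")
    stop = df["trial_type"] == "stop"
    if df.loc[stop, "ssd"].isna().any():
        raise ValueError("stop trial with missing SSD")
    if df.loc[~stop, "ssd"].notna().any():
        raise ValueError("go trial with an SSD")
    has_rt = df["rt"].notna()
    if (has_rt & (df["response_hand"] == "none")).any():
        raise ValueError("RT present without a response hand")
    if (has_rt & (df["rt"] > response_window)).any():
        raise ValueError(f"RT beyond the {response_window:.0f} ms response window")
    df["outcome"] = [
        derive_outcome(t, req, resp, rt)
        for t, req, resp, rt in zip(
            df["trial_type"], df["required_hand"], df["response_hand"], df["rt"]
        )
    ]
    return df


def read_trial_table(path) -> pd.DataFrame:
    """Read a tab-separated trial table (go_onset in s; ssd/rt in ms)."""
    df = pd.read_csv(path, sep="\t")
    return validate_trial_table(df)


def write_trial_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# continuous-recording readers
# ---------------------------------------------------------------------------

def _read_brainvision(path: Path, hand_map: dict | None) -> ContinuousRecording:
    import mne

    path = Path(path)
    for ext in (".vmrk", ".eeg"):
        member = path.with_suffix(ext)
        if not member.exists():
            raise FileNotFoundError(
                f"BrainVision triplet incomplete: marker/data file absent ({member.name})"
            )
    raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # mne returns volts
    events = [
        (float(on), desc.split("/")[-1])
        for on, desc in zip(raw.annotations.onset, raw.annotations.description)
        if not desc.startswith("New Segment")
    ]
    return ContinuousRecording(
        samples=samples,
        rate=float(raw.info["sfreq"]),
        channels=list(raw.ch_names),
        hand_map=dict(hand_map or {}),
        events=events,
        meta={"source": str(path), "format": "brainvision"},
    )


def _read_delimited(path: Path, hand_map: dict | None) -> ContinuousRecording:
    path = Path(path)
    sidecar = path.with_suffix(".yaml")
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar absent: {sidecar.name}")
    with open(sidecar) as fh:
        side = yaml.safe_load(fh)
    units = side.get("units", "uV")
    if units not in ("uV", "µV", "microvolts"):
        raise ValueError(f"unknown units {units!r}")
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] == 0:
        raise ValueError("recording has zero channels")
    events = [(float(t), str(code)) for t, code in side.get("events", [])]
    return ContinuousRecording(
        samples=df.to_numpy().T,
        rate=float(side["rate"]),
        channels=list(df.columns),
        hand_map=dict(hand_map or side.get("channels", {})),
        events=events,
        meta={"source": str(path), "format": "delimited"},
    )


def read_continuous_recording(path, format: str = "brainvision", hand_map: dict | None = None) -> ContinuousRecording:
    """Read a continuous EMG recording.

    ``format="brainvision"`` expects the .vhdr of a .vhdr/.eeg/.vmrk triplet;
    ``format="delimited"`` expects a tab-separated file (one column per
    channel) with a ``.yaml`` sidecar declaring rate, units and the
    channel->hand map.
    """
    if format == "brainvision":
        return _read_brainvision(Path(path), hand_map)
    if format == "delimited":
        return _read_delimited(Path(path), hand_map)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# burst table / summary serialization
# ---------------------------------------------------------------------------

def write_burst_table(bursts: pd.DataFrame, path) -> None:
    """Write a per-trial burst table as CSV (missing values -> empty fields)."""
    cols = [c for c in BURST_COLUMNS if c in bursts.columns]
    cols += [c for c in bursts.columns if c not in cols]
    bursts.loc[:, cols].to_csv(path, index=False, na_rep="")


def read_burst_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("detected", "onset_at_window_start", "pre_stop_peak"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


@dataclass
class ParticipantSummary:
    """Per-participant behavioral and EMG summary blocks.

    Values are plain floats (or NaN when undefined, e.g. prEMG latency of a
    participant without prEMG trials); keys are flat metric names.
    """

    participant: str
    behavioral: dict = field(default_factory=dict)
    emg: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, val in {**self.behavioral, **self.emg}.items():
            if key.endswith("_pct") and np.isfinite(val) and not (0.0 <= val <= 100.0):
                raise ValueError(f"{key} outside [0, 100]: {val}")

    def to_row(self) -> dict:
        row = {"participant": self.participant}
        row.update({f"beh_{k}": v for k, v in self.behavioral.items()})
        row.update({f"emg_{k}": v for k, v in self.emg.items()})
        return row


def write_summary(summaries: Sequence[ParticipantSummary] | ParticipantSummary, path) -> None:
    """Write one CSV row per participant; absent estimates stay empty."""
    if isinstance(summaries, ParticipantSummary):
        summaries = [summaries]
    pd.DataFrame([s.to_row() for s in summaries]).to_csv(path, index=False, na_rep="")


def read_summary(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json_report(report: dict, path) -> None:
    def _default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(type(obj))

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default, allow_nan=True)
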