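"""Continuous EMG -> z-scored RMS-envelope epochs.

The chain is: band-pass filter at the native rate, decimate to 500 Hz, epoch
around go-signal onsets, reject trials with excessive baseline activity,
moving-window RMS envelope, per-trial baseline normalization, and block-wise
z-scoring. Stage order is enforced; applying a step out of order raises
:class:`~premg.data_model.StageError`.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .data_model import ContinuousRecording, EpochSet

__all__ = [
    "PreprocessConfig",
    "bandpass",
    "resample",
    "epoch",
    "reject_high_baseline",
    "rms_envelope",
    "baseline_normalize",
    "zscore_by_block",
    "preprocess_participant",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Numeric defaults of the preprocessing chain.

    band : (low, high) band-pass edges, Hz
    filter_order : Butterworth design order (per edge), 2
    target_rate : Hz after decimation
    epoch_window : (start, end) s relative to go onset
    baseline_window : (start, end) s, must lie inside the epoch window
    reject_baseline_uv : mean rectified baseline amplitude cut-off, microvolts
    rms_halfwidth : half-width of the centered RMS window, samples
    zero_phase : forward-backward filtering (True) keeps burst latencies
        undelayed; set False for causal filtering.
    """

    band: tuple = (20.0, 250.0)
    filter_order: int = 2
    target_rate: float = 500.0
    epoch_window: tuple = (-0.2, 1.6)
    baseline_window: tuple = (-0.2, 0.0)
    reject_baseline_uv: float = 100.0
    rms_halfwidth: int = 5
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.band[1] > self.target_rate / 2:
            raise ValueError("upper band edge above the target Nyquist frequency")
        bw, ew = self.baseline_window, self.epoch_window
        if not (ew[0] <= bw[0] < bw[1] <= ew[1]):
            raise ValueError("baseline window must lie inside the epoch window")
        if self.rms_halfwidth < 0:
            raise ValueError("rms_halfwidth must be >= 0")


def bandpass(recording: ContinuousRecording, config: PreprocessConfig = PreprocessConfig()) -> ContinuousRecording:
    """Band-pass filter each channel (zero-phase Butterworth by default)."""
    low, high = config.band
    if recording.rate <= 2 * high:
        raise ValueError(
            f"sampling rate {recording.rate} Hz too low for a {high} Hz band edge"
        )
    sos = signal.butter(
        config.filter_order, [low, high], btype="bandpass", fs=recording.rate, output="sos"
    )
    if config.zero_phase:
        filtered = signal.sosfiltfilt(sos, recording.samples, axis=1)
    else:
        filtered = signal.sosfilt(sos, recording.samples, axis=1)
    return ContinuousRecording(
        samples=filtered,
        rate=recording.rate,
        channels=list(recording.channels),
        hand_map=dict(recording.hand_map),
        events=list(recording.events),
        meta={**recording.meta, "bandpass": (low, high), "zero_phase": config.zero_phase},
    )


def resample(recording: ContinuousRecording, target_rate: float = 500.0) -> ContinuousRecording:
    """Decimate to ``target_rate`` (rational ratios handled; no upsampling).

    Event times are in seconds and therefore unchanged by the new clock.
    """
    if target_rate > recording.rate:
        raise ValueError("upsampling is not supported")
    if target_rate == recording.rate:
        return recording
    ratio = Fraction(target_rate / recording.rate).limit_denominator(10000)
    out = signal.resample_poly(recording.samples, ratio.numerator, ratio.denominator, axis=1)
    return ContinuousRecording(
        samples=out,
        rate=float(target_rate),
        channels=list(recording.channels),
        hand_map=dict(recording.hand_map),
        events=list(recording.events),
        meta={**recording.meta, "resampled_from": recording.rate},
    )


def epoch(recording: ContinuousRecording, trials: pd.DataFrame, config: PreprocessConfig = PreprocessConfig()) -> EpochSet:
    """Cut go-locked epochs, one per trial, from the required hand's channel.

    Trials whose window exceeds the recording bounds are flagged rejected
    with reason ``"edge"`` (their rows are zero-filled placeholders).
    """
    t0, t1 = config.epoch_window
    rate = recording.rate
    n_samp = int(round((t1 - t0) * rate))
    time = t0 + np.arange(n_samp) / rate
    data = np.zeros((len(trials), n_samp))
    rejected: dict = {}
    for row_i, trial in enumerate(trials.itertuples(index=False)):
        ch = recording.channel_for_hand(trial.required_hand)
        start = int(round((trial.go_onset + t0) * rate))
        stop = start + n_samp
        if start < 0 or stop > recording.n_samples:
            rejected[trial.trial_id] = "edge"
            continue
        data[row_i] = recording.samples[ch, start:stop]
    return EpochSet(
        data=data,
        time=time,
        rate=rate,
        stage="filtered",
        trial_ids=trials["trial_id"].to_numpy(),
        hands=trials["required_hand"].to_numpy(),
        blocks=trials["block"].to_numpy(),
        rejected=rejected,
    )


def _window_mask(time: np.ndarray, window: tuple) -> np.ndarray:
    return (time >= window[0] - 1e-12) & (time < window[1] - 1e-12)


def reject_high_baseline(epochs: EpochSet, config: PreprocessConfig = PreprocessConfig()) -> EpochSet:
    """Flag trials whose mean rectified baseline amplitude exceeds the cut-off.

    Applied on the filtered (pre-envelope) signal; rectification makes the
    microvolt criterion sign-invariant.
    """
    epochs.require_stage("filtered")
    mask = _window_mask(epochs.time, config.baseline_window)
    level = np.abs(epochs.data[:, mask]).mean(axis=1)
    rejected = dict(epochs.rejected)
    for tid, lev in zip(epochs.trial_ids, level):
        if tid not in rejected and lev > config.reject_baseline_uv:
            rejected[tid] = "baseline"
    out = EpochSet(
        data=epochs.data.copy(),
        time=epochs.time,
        rate=epochs.rate,
        stage="filtered",
        trial_ids=epochs.trial_ids.copy(),
        hands=epochs.hands.copy(),
        blocks=epochs.blocks.copy(),
        rejected=rejected,
    )
    return out


def rms_envelope(epochs: EpochSet, halfwidth: int = 5) -> EpochSet:
    """Moving-window RMS: each sample becomes the RMS over a centered
    ``2*halfwidth + 1`` sample window; the window truncates at epoch edges
    rather than padding with fabricated data.
    """
    epochs.require_stage("filtered")
    n = epochs.data.shape[1]
    if halfwidth >= n:
        raise ValueError("halfwidth must be smaller than the epoch length")
    sq = epochs.data**2
    csum = np.cumsum(sq, axis=1)
    csum = np.concatenate([np.zeros((sq.shape[0], 1)), csum], axis=1)
    idx = np.arange(n)
    lo = np.maximum(idx - halfwidth, 0)
    hi = np.minimum(idx + halfwidth, n - 1) + 1
    window_sums = csum[:, hi] - csum[:, lo]
    out = np.sqrt(window_sums / (hi - lo))
    return epochs.advance(out, "rms")


def baseline_normalize(epochs: EpochSet, config: PreprocessConfig = PreprocessConfig()) -> EpochSet:
    """Divide each trial's envelope by its own baseline-window mean.

    A zero baseline mean (flat signal) flags the trial rejected
    ("flat baseline") instead of dividing by zero.
    """
    epochs.require_stage("rms")
    mask = _window_mask(epochs.time, config.baseline_window)
    base = epochs.data[:, mask].mean(axis=1)
    out = np.array(epochs.data, copy=True)
    new_rejected = dict(epochs.rejected)
    for i, (tid, b) in enumerate(zip(epochs.trial_ids, base)):
        if b > 0:
            out[i] = out[i] / b
        elif tid not in new_rejected:
            new_rejected[tid] = "flat baseline"
    result = epochs.advance(out, "baseline_normalized")
    result.rejected = new_rejected
    return result


def zscore_by_block(epochs: EpochSet) -> EpochSet:
    """Z-score all samples of each (hand, block) group over the concatenated
    non-rejected epochs of that group (population sd, divisor N).

    Rejected trials are excluded from the statistics but transformed with
    the group's mean/sd so that their rows remain aligned.
    """
    epochs.require_stage("baseline_normalized")
    out = np.array(epochs.data, copy=True)
    kept = epochs.kept_mask()
    for hand in np.unique(epochs.hands):
        for block in np.unique(epochs.blocks):
            rows = (epochs.hands == hand) & (epochs.blocks == block)
            stat_rows = rows & kept
            if not stat_rows.any():
                continue
            pool = epochs.data[stat_rows].ravel()
            mu = pool.mean()
            sd = pool.std(ddof=0)
            if sd == 0:
                raise ValueError(
                    f"zero variance in block {block} ({hand} hand); cannot z-score"
                )
            out[rows] = (epochs.data[rows] - mu) / sd
    return epochs.advance(out, "zscored")


def preprocess_participant(
    recording: ContinuousRecording,
    trials: pd.DataFrame,
    config: PreprocessConfig = PreprocessConfig(),
) -> EpochSet:
    """Run the full documented chain on one participant's recording."""
    rec = bandpass(recording, config)
    rec = resample(rec, config.target_rate)
    ep = epoch(rec, trials, config)
    ep = reject_high_baseline(ep, config)
    ep = rms_envelope(ep, config.rms_halfwidth)
    ep = baseline_normalize(ep, config)
    return zscore_by_block(ep)
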