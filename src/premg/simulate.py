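"""Stop-signal-task simulator with ground-truth EMG bursts.

Behavior follows the independent horse race: on every trial a go finishing
time is drawn; on stop trials a stop finishing time races against it from
stop-signal onset, and the response is emitted only if the go process wins.
The stop-signal delay (SSD) is adapted by the standard one-up/one-down
staircase (initial 250 ms, step 50 ms, bounds 100-800 ms), which converges
to ~50% successful stopping. Go failures (no response at all) and trigger
failures (the stop process never starts) occur with small probabilities.

The EMG layer adds, on top of band-limited noise, an amplitude-modulated
burst for every trial in which the go process reached the muscle: full
bursts on responded trials and truncated bursts (prEMG) on successful stop
trials whose muscle activity started before the peripheral stop latency
took effect. Ground-truth onset/peak times and flags are recorded so that
every downstream stage can be validated against them.

One global seed expands deterministically into per-participant streams, so
any subset of participants is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .data_model import ContinuousRecording, validate_trial_table, write_trial_table

__all__ = [
    "SimConfig",
    "EmgConfig",
    "staircase_update",
    "simulate_behavior",
    "synthesize_emg",
    "simulate_participant_emg",
    "make_fixture",
    "write_brainvision",
]


@dataclass(frozen=True)
class SimConfig:
    """Task and race-model parameters.

    Defaults reproduce the study conditions: 46 participants, 684 go + 216
    stop trials (24% stop) in 6 blocks; go finishing times with mean 546 ms
    and within-participant sd 114 ms (participant means jittered with sd
    77 ms); stop latencies 202/31 ms (between-participant sd 21 ms); go and
    trigger failure rates 1.6% / 1.3%; staircase 250 ms initial, 50 ms
    steps, clamped to [100, 800] ms; motor time (EMG onset to registered
    press) 57/13 ms; 1000 ms response window.

    ``dependence="onset_coupled"`` adds a positive coupling between the
    go-locked muscle onset and the stop-locked truncation latency
    (single-trial association scenario); ``independent`` keeps them
    unrelated.
    """

    n_participants: int = 46
    n_go: int = 684
    n_stop: int = 216
    n_blocks: int = 6
    go_mean: float = 546.0
    go_sd: float = 114.0
    stop_mean: float = 202.0
    stop_sd: float = 31.0
    between_subject_go_sd: float = 77.0
    between_subject_stop_sd: float = 21.0
    p_go_failure: float = 0.016
    p_trigger_failure: float = 0.013
    p_choice_error: float = 0.007
    staircase_init: float = 250.0
    staircase_step: float = 50.0
    staircase_min: float = 100.0
    staircase_max: float = 800.0
    motor_time_mean: float = 57.0
    motor_time_sd: float = 13.0
    dependence: str = "independent"
    coupling: float = 0.5
    response_window: float = 1000.0
    trial_spacing: float = 2.25  # go-onset to go-onset, s
    spacing_jitter: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("go_mean", "go_sd", "stop_mean", "stop_sd",
                     "motor_time_mean", "motor_time_sd", "response_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_go_failure", "p_trigger_failure", "p_choice_error"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if not (self.staircase_min <= self.staircase_init <= self.staircase_max):
            raise ValueError("staircase bounds must bracket the initial SSD")
        if self.dependence not in ("independent", "onset_coupled"):
            raise ValueError(f"unknown dependence mode {self.dependence!r}")


@dataclass(frozen=True)
class EmgConfig:
    """EMG synthesis parameters (the package's own generative model of the
    thumb-muscle signal).

    The signal is band-limited Gaussian noise (``noise_sd`` microvolts RMS)
    plus, per initiated response, a burst: band-limited carrier noise
    multiplied by an envelope that rises linearly over ``burst_rise`` ms to
    ``burst_amp`` microvolts and decays linearly over ``burst_fall`` ms.
    PrEMG bursts are truncated at SSD + peripheral stop latency
    (``premg_mean``/``premg_sd`` ms after the stop signal) with amplitude
    proportional to the accumulation time; truncated bursts accumulating
    less than ``premg_min_accumulation_ms`` are treated as no muscle output.
    """

    rate: float = 5000.0
    noise_sd: float = 8.0
    burst_amp: float = 200.0
    burst_rise: float = 52.0
    burst_rise_shape: float = 0.5  # <1: fast initial recruitment, concave rise
    burst_fall: float = 80.0
    premg_mean: float = 165.0
    premg_sd: float = 31.0  # within-participant trial-to-trial dispersion
    premg_between_sd: float = 21.0  # between-participant dispersion of the mean
    premg_min_accumulation_ms: float = 6.0
    premg_amp_cap: float = 0.9  # fraction of burst_amp; keeps prEMG < go-EMG
    carrier_band: tuple = (20.0, 250.0)
    carrier: str = "noise"  # "noise": stochastic EMG-like; "tone": deterministic
    tone_freq: float = 80.0  # Hz, used by the tone carrier

    def __post_init__(self) -> None:
        if self.burst_amp <= self.noise_sd:
            raise ValueError("burst amplitude must exceed the noise floor")
        if self.burst_rise <= 0 or self.burst_fall <= 0:
            raise ValueError("rise and fall times must be positive")
        if self.carrier not in ("noise", "tone"):
            raise ValueError(f"unknown carrier {self.carrier!r}")


TRUTH_COLUMNS = [
    "trial_id",
    "go_finish",
    "stop_finish",
    "go_failure",
    "trigger_failure",
    "emg_onset",
    "emg_peak",
    "emg_amp",
    "premg_true",
    "motor_time_true",
]


def staircase_update(ssd: float, success: bool, step: float = 50.0,
                     lo: float = 100.0, hi: float = 800.0) -> float:
    """One staircase move: +step after a successful stop, -step after a
    failed stop, clamped to [lo, hi]."""
    nxt = ssd + step if success else ssd - step
    return float(min(max(nxt, lo), hi))


def participant_streams(seed: int, n: int) -> list:
    """Deterministic per-participant random streams from one global seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _trial_order(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Randomized go/stop order; the first block starts with >= 10 go trials."""
    types = np.array(["go"] * cfg.n_go + ["stop"] * cfg.n_stop)
    rng.shuffle(types)
    lead = min(10, cfg.n_go)
    is_stop = types == "stop"
    head_stops = np.nonzero(is_stop[:lead])[0]
    tail_gos = np.nonzero(~is_stop[lead:])[0] + lead
    for h, t in zip(head_stops, tail_gos[::-1]):
        types[h], types[t] = types[t], types[h]
    return types


def simulate_behavior(cfg: SimConfig = SimConfig(), seed: int | None = None):
    """Simulate the cohort's behavior.

    Returns ``(trials, truth)``: a trial table (one row per trial with a
    ``participant`` column, go onsets on each participant's recording
    clock) and the matching ground-truth table.
    """
    seed = cfg.seed if seed is None else seed
    streams = participant_streams(seed, cfg.n_participants)
    all_trials, all_truth = [], []
    for p_idx, rng in enumerate(streams):
        pid = f"sub-{p_idx + 1:02d}"
        go_mu = cfg.go_mean + rng.normal(0.0, cfg.between_subject_go_sd)
        stop_mu = cfg.stop_mean + rng.normal(0.0, cfg.between_subject_stop_sd)
        go_mu = max(go_mu, 150.0)
        stop_mu = max(stop_mu, 50.0)
        types = _trial_order(cfg, rng)
        n_trials = len(types)
        block_size = int(np.ceil(n_trials / cfg.n_blocks))
        # per-trial draws are vectorized; only the staircase is sequential
        go_finish_v = np.maximum(rng.normal(go_mu, cfg.go_sd, n_trials), 1.0)
        go_fail_v = rng.random(n_trials) < cfg.p_go_failure
        choice_err_v = rng.random(n_trials) < cfg.p_choice_error
        motor_v = np.maximum(
            rng.normal(cfg.motor_time_mean, cfg.motor_time_sd, n_trials), 1.0)
        stop_finish_v = np.maximum(rng.normal(stop_mu, cfg.stop_sd, n_trials), 1.0)
        trig_fail_v = rng.random(n_trials) < cfg.p_trigger_failure
        onsets = 1.0 + np.concatenate([
            [0.0],
            np.cumsum(cfg.trial_spacing
                      + rng.uniform(-cfg.spacing_jitter, cfg.spacing_jitter,
                                    n_trials - 1)),
        ])
        ssd = cfg.staircase_init
        hand_cycle = ("left", "right")
        rows, truths = [], []
        for i, ttype in enumerate(types):
            trial_id = f"{pid}_t{i + 1:04d}"
            required = hand_cycle[i % 2]
            go_finish = go_finish_v[i]
            go_fail = bool(go_fail_v[i])
            stop_finish = np.nan
            trig_fail = False
            this_ssd = np.nan
            if ttype == "stop":
                this_ssd = ssd
                trig_fail = bool(trig_fail_v[i])
                stop_finish = stop_finish_v[i]
                go_wins = trig_fail or (go_finish < this_ssd + stop_finish)
                responded = (not go_fail) and go_wins and go_finish <= cfg.response_window
                ssd = staircase_update(
                    this_ssd, success=not responded, step=cfg.staircase_step,
                    lo=cfg.staircase_min, hi=cfg.staircase_max,
                )
            else:
                responded = (not go_fail) and go_finish <= cfg.response_window
            resp_hand = "none"
            rt = np.nan
            if responded:
                rt = go_finish
                resp_hand = (
                    hand_cycle[(i + 1) % 2]
                    if (ttype == "go" and choice_err_v[i]) else required
                )
            rows.append({
                "trial_id": trial_id,
                "participant": pid,
                "block": i // block_size,
                "trial_type": ttype,
                "go_onset": onsets[i],
                "ssd": this_ssd,
                "required_hand": required,
                "response_hand": resp_hand,
                "rt": rt,
            })
            truths.append({
                "trial_id": trial_id,
                "participant": pid,
                "go_finish": go_finish,
                "stop_finish": stop_finish,
                "go_failure": go_fail,
                "trigger_failure": trig_fail,
                "emg_onset": np.nan,
                "emg_peak": np.nan,
                "emg_amp": np.nan,
                "premg_true": False,
                "motor_time_true": motor_v[i],
            })
        trials = validate_trial_table(pd.DataFrame(rows), cfg.response_window)
        all_trials.append(trials)
        all_truth.append(pd.DataFrame(truths))
    return (
        pd.concat(all_trials, ignore_index=True),
        pd.concat(all_truth, ignore_index=True),
    )


def _band_noise(n: int, rate: float, band: tuple, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise."""
    sos = signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _envelope(t: np.ndarray, onset_s: float, peak_s: float, amp: float,
              fall_ms: float, shape: float = 0.5) -> np.ndarray:
    """Burst envelope: concave power-law rise onset->peak (fast initial
    motor-unit recruitment), linear fall peak->end."""
    env = np.zeros(t.size)
    rise = peak_s - onset_s
    end = peak_s + fall_ms / 1000.0
    up = (t >= onset_s) & (t < peak_s)
    env[up] = amp * ((t[up] - onset_s) / max(rise, 1e-9)) ** shape
    down = (t >= peak_s) & (t < end)
    env[down] = amp * (1.0 - (t[down] - peak_s) / (fall_ms / 1000.0))
    return env


def synthesize_emg(trials: pd.DataFrame, truth: pd.DataFrame,
                   emg: EmgConfig = EmgConfig(),
                   cfg: SimConfig = SimConfig(),
                   rng: np.random.Generator | None = None):
    """Render one participant's continuous two-channel EMG.

    Responded trials get a full burst with onset at RT - motor time and
    peak one rise time later. Successful stop trials in which the go
    process would have initiated muscle output before SSD + peripheral stop
    latency get a truncated burst (prEMG) whose amplitude grows with the
    accumulation time; a trial accumulating less than the configured
    minimum is treated as muscle-silent. Returns the recording and the
    truth table updated with exact onset/peak times (seconds, recording
    clock) and amplitudes.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    # this participant's characteristic peripheral stop latency: individual
    # differences in stopping speed reach the muscle too
    psl_base = rng.normal(emg.premg_mean, emg.premg_between_sd)
    truth = truth.copy().set_index("trial_id")
    duration = float(trials["go_onset"].max()) + 2.0
    n = int(round(duration * emg.rate))
    chans = {"left": _band_noise(n, emg.rate, emg.carrier_band, rng) * emg.noise_sd,
             "right": _band_noise(n, emg.rate, emg.carrier_band, rng) * emg.noise_sd}
    events = []
    for trial in trials.itertuples(index=False):
        events.append((float(trial.go_onset), "go"))
        if trial.trial_type == "stop":
            events.append((trial.go_onset + trial.ssd / 1000.0, "stop"))
        tr = truth.loc[trial.trial_id]
        if tr["go_failure"]:
            continue
        onset_ms = tr["go_finish"] - tr["motor_time_true"]
        amp = None
        if trial.trial_type == "go" or trial.response_hand != "none":
            # go process reached the muscle and was never countermanded
            peak_ms = onset_ms + emg.burst_rise
            amp = emg.burst_amp
        elif not tr["trigger_failure"]:  # stop trial without a response
            psl = psl_base + rng.normal(0.0, emg.premg_sd)
            if cfg.dependence == "onset_coupled":
                psl += cfg.coupling * (onset_ms - (cfg.go_mean - cfg.motor_time_mean))
            peak_ms = trial.ssd + psl
            accum = peak_ms - onset_ms
            if accum >= emg.premg_min_accumulation_ms:
                # amplitude reached on the full-burst rise curve at truncation
                frac = (accum / emg.burst_rise) ** emg.burst_rise_shape
                amp = emg.burst_amp * min(frac, emg.premg_amp_cap)
                truth.loc[trial.trial_id, "premg_true"] = True
        if amp is None:
            continue
        onset_s = trial.go_onset + onset_ms / 1000.0
        peak_s = trial.go_onset + peak_ms / 1000.0
        lo = max(int((onset_s - 0.05) * emg.rate), 0)
        hi = min(int((peak_s + emg.burst_fall / 1000.0 + 0.05) * emg.rate), n)
        if hi <= lo:
            continue  # burst would fall past the recording end
        seg_t = np.arange(lo, hi) / emg.rate
        env = _envelope(seg_t, onset_s, peak_s, amp, emg.burst_fall,
                        emg.burst_rise_shape)
        if emg.carrier == "tone":
            carrier = np.sqrt(2.0) * np.sin(2 * np.pi * emg.tone_freq * seg_t)
        else:
            carrier = _band_noise(hi - lo, emg.rate, emg.carrier_band, rng)
        hand = trial.required_hand
        chans[hand][lo:hi] += env * carrier
        truth.loc[trial.trial_id, "emg_onset"] = onset_s
        truth.loc[trial.trial_id, "emg_peak"] = peak_s
        truth.loc[trial.trial_id, "emg_amp"] = amp
    rec = ContinuousRecording(
        samples=np.vstack([chans["left"], chans["right"]]),
        rate=emg.rate,
        channels=["EMG_left", "EMG_right"],
        hand_map={"EMG_left": "left", "EMG_right": "right"},
        events=sorted(events),
        meta={"synthetic": True},
    )
    return rec, truth.reset_index()


def simulate_participant_emg(cfg: SimConfig, emg: EmgConfig, participant_index: int = 0,
                             seed: int | None = None):
    """Behavior + EMG for a single participant, reproducible from the
    global seed regardless of cohort size."""
    seed = cfg.seed if seed is None else seed
    one = replace(cfg, n_participants=participant_index + 1, seed=seed)
    trials, truth = simulate_behavior(one)
    pid = f"sub-{participant_index + 1:02d}"
    trials = trials[trials["participant"] == pid].reset_index(drop=True)
    truth = truth[truth["participant"] == pid].reset_index(drop=True)
    emg_rng = np.random.default_rng(
        np.random.SeedSequence(seed).spawn(participant_index + 1)[participant_index]
        .spawn(2)[1]
    )
    rec, truth = synthesize_emg(trials, truth, emg, cfg, emg_rng)
    return trials, truth, rec


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def write_brainvision(rec: ContinuousRecording, stem: Path) -> Path:
    """Write a BrainVision triplet (.vhdr/.vmrk/.eeg, IEEE float32
    multiplexed); readable by standard electrophysiology readers."""
    stem = Path(stem)
    vhdr, vmrk, eeg = (stem.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    ch_lines = "\n".join(
        f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(rec.channels)
    )
    vhdr.write_text(
        "Brain Vision Data Exchange Header File Version 1.0\n\n"
        "[Common Infos]\nCodepage=UTF-8\n"
        f"DataFile={eeg.name}\nMarkerFile={vmrk.name}\n"
        "DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n"
        f"NumberOfChannels={len(rec.channels)}\n"
        f"SamplingInterval={1e6 / rec.rate:.6f}\n\n"
        "[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n\n"
        f"[Channel Infos]\n{ch_lines}\n",
        encoding="utf-8",
    )
    marks = ["Mk1=New Segment,,1,1,0,0"]
    for k, (t, code) in enumerate(rec.events, start=2):
        pos = int(round(t * rec.rate)) + 1  # marker positions are 1-based
        marks.append(f"Mk{k}=Stimulus,{code},{pos},1,0")
    vmrk.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n\n"
        "[Common Infos]\nCodepage=UTF-8\n"
        f"DataFile={eeg.name}\n\n"
        "[Marker Infos]\n" + "\n".join(marks) + "\n",
        encoding="utf-8",
    )
    rec.samples.T.astype(np.float32).tofile(eeg)
    return vhdr


def write_delimited(rec: ContinuousRecording, stem: Path) -> Path:
    """Write the recording as TSV (one column per channel) + YAML sidecar."""
    stem = Path(stem)
    tsv = stem.with_suffix(".tsv")
    pd.DataFrame(rec.samples.T, columns=rec.channels).to_csv(tsv, sep="\t", index=False)
    stem.with_suffix(".yaml").write_text(yaml.safe_dump({
        "rate": float(rec.rate),
        "units": "uV",
        "channels": dict(rec.hand_map),
        "events": [[float(t), str(c)] for t, c in rec.events],
    }))
    return tsv


def make_fixture(cfg: SimConfig, emg: EmgConfig, out_dir, fmt: str = "brainvision") -> dict:
    """Write per-participant recording + trial table + ground truth files.

    Deterministic for a given ``cfg.seed``. Returns a manifest mapping
    participant -> file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for idx in range(cfg.n_participants):
        trials, truth, rec = simulate_participant_emg(cfg, emg, idx)
        pid = trials["participant"].iloc[0]
        stem = out_dir / f"{pid}_emg"
        if fmt == "brainvision":
            rec_path = write_brainvision(rec, stem)
        elif fmt == "delimited":
            rec_path = write_delimited(rec, stem)
        else:
            raise ValueError(f"unknown fixture format {fmt!r}")
        trial_path = out_dir / f"{pid}_events.tsv"
        write_trial_table(trials, trial_path)
        truth_path = out_dir / f"{pid}_truth.csv"
        truth.to_csv(truth_path, index=False, na_rep="")
        manifest[pid] = {
            "recording": str(rec_path),
            "trials": str(trial_path),
            "truth": str(truth_path),
        }
    return manifest
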