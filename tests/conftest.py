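import numpy as np
import pandas as pd
import pytest

from premg.burst_detect import extract_bursts
from premg.preprocess import preprocess_participant
from premg.simulate import EmgConfig, SimConfig, simulate_participant_emg

# EMG-bearing fixtures run the synthesizer at 2 kHz with a few hundred
# trials: enough for stable rates/latencies while keeping the suite fast.
MINI_SIM = SimConfig(n_participants=1, n_go=150, n_stop=50, seed=7)
MINI_EMG = EmgConfig(rate=2000.0)


@pytest.fixture(scope="session")
def mini_participant():
    """One simulated participant taken through the full chain."""
    trials, truth, rec = simulate_participant_emg(MINI_SIM, MINI_EMG, 0)
    epochs = preprocess_participant(rec, trials)
    bursts = extract_bursts(epochs, trials)
    return {"trials": trials, "truth": truth, "recording": rec,
            "epochs": epochs, "bursts": bursts}


@pytest.fixture(scope="session")
def cohort_behavior():
    """Behavior-only cohort at study scale (no EMG)."""
    from premg.simulate import simulate_behavior

    cfg = SimConfig(seed=13)
    trials, truth = simulate_behavior(cfg)
    return trials, truth


def make_trials(rows):
    """Tiny hand-written trial table helper."""
    from premg.data_model import validate_trial_table

    df = pd.DataFrame(rows, columns=[
        "trial_id", "block", "trial_type", "go_onset", "ssd",
        "required_hand", "response_hand", "rt",
    ])
    return validate_trial_table(df)
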