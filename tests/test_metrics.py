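"""SSRT, prEMG latency estimators, inhibition functions, partitions,
single-trial preparation and variability."""

import numpy as np
import pandas as pd
import pytest

from premg.metrics import (
    behavioral_summary,
    centered_ssd_steps,
    hand_averaged,
    inhibition_functions,
    modal_ssd,
    partition_go_distribution,
    peak_latency_variability,
    premg_peak_latency,
    single_trial_prepare,
    ssd_profiles,
    ssrt_integration,
)

from conftest import make_trials


def _trials_from_vectors(go_rts, stop_responded, ssds, omissions=0):
    rows = []
    for i, rt in enumerate(go_rts):
        rows.append((f"g{i}", 0, "go", 1.0 + 2 * i, np.nan, "left", "left", rt))
    for i in range(omissions):
        rows.append((f"o{i}", 0, "go", 500.0 + 2 * i, np.nan, "left", "none", np.nan))
    for i, (resp, ssd) in enumerate(zip(stop_responded, ssds)):
        hand = "left" if resp else "none"
        rt = 600.0 if resp else np.nan
        rows.append((f"s{i}", 0, "stop", 1000.0 + 2 * i, ssd, "left", hand, rt))
    return make_trials(rows)


def test_ssrt_integration_hand_computed():
    """10 go RTs 100..1000, p(respond|stop)=0.5, mean SSD 300: the rank-5
    quantile is 500, so SSRT = 200 ms."""
    go_rts = [100.0 * k for k in range(1, 11)]
    trials = _trials_from_vectors(go_rts, [True, False] * 5, [300.0] * 10)
    res = ssrt_integration(trials)
    assert res.valid
    assert res.p_respond == 0.5
    assert res.ssrt == pytest.approx(200.0)


def test_ssrt_omission_replaced_by_max_rt():
    """Replacing one go RT by an omission substitutes the participant's
    maximum RT: recomputed by hand, rank 5 of {200..900,1000,1000} is 600."""
    go_rts = [100.0 * k for k in range(2, 11)]  # 200..1000
    trials = _trials_from_vectors(go_rts, [True, False] * 5, [300.0] * 10,
                                  omissions=1)
    res = ssrt_integration(trials)
    vec = sorted(go_rts + [1000.0])
    assert res.ssrt == pytest.approx(vec[4] - 300.0)
    assert res.ssrt == pytest.approx(300.0)


def test_ssrt_undefined_when_all_stops_fail():
    trials = _trials_from_vectors([400.0, 500.0], [True, True], [250.0, 250.0])
    res = ssrt_integration(trials)
    assert not res.valid
    assert np.isnan(res.ssrt)


def test_behavioral_summary_counts():
    rows = [(f"g{i}", 0, "go", 1.0 + i, np.nan, "left", "left", 400.0)
            for i in range(9)]
    rows.append(("g9", 0, "go", 20.0, np.nan, "left", "none", np.nan))
    rows += [(f"s{i}", 0, "stop", 30.0 + i, 250.0, "left",
              "left" if i < 4 else "none", 500.0 if i < 4 else np.nan)
             for i in range(8)]
    summary = behavioral_summary(make_trials(rows))
    assert summary["go_accuracy_pct"] == pytest.approx(90.0)
    assert summary["go_omission_pct"] == pytest.approx(10.0)
    assert summary["stop_accuracy_pct"] == pytest.approx(50.0)
    assert summary["ustop_rt"] == pytest.approx(500.0)


def _bursts(rows):
    return pd.DataFrame(rows, columns=[
        "trial_id", "detected", "onset_go", "peak_go", "peak_stop",
        "peak_amp", "motor_time", "rise_time", "auc", "emg_class",
        "onset_at_window_start", "pre_stop_peak",
    ])


def test_premg_latency_single_trial_is_mean_of_peaks():
    trials = _trials_from_vectors([400.0], [False, False], [300.0, 300.0])
    bursts = _bursts([
        ("s0", True, 350.0, 450.0, 150.0, 3.0, np.nan, 100.0, 5.0, "premg", False, False),
        ("s1", True, 370.0, 470.0, 170.0, 3.0, np.nan, 100.0, 5.0, "premg", False, False),
    ])
    assert premg_peak_latency(bursts, trials, "single_trial") == pytest.approx(160.0)


def test_premg_latency_absent_without_premg_trials():
    trials = _trials_from_vectors([400.0], [True], [300.0])
    bursts = _bursts([])
    assert np.isnan(premg_peak_latency(bursts, trials, "single_trial"))


def test_modal_ssd_tie_goes_to_lowest():
    assert modal_ssd(pd.Series([200.0, 200.0, 300.0, 300.0, 400.0])) == 200.0


def test_premg_latency_estimators_agree_on_identical_epochs(mini_participant):
    """The three estimators all derive from the same stop-locked peaks, so
    on real simulated data they agree within the latency spread; on a
    participant with identical per-trial peaks they agree exactly."""
    trials = mini_participant["trials"]
    bursts = mini_participant["bursts"]
    epochs = mini_participant["epochs"]
    st = premg_peak_latency(bursts, trials, "single_trial")
    avg = premg_peak_latency(bursts, trials, "average_waveform", epochs)
    mode = premg_peak_latency(bursts, trials, "mode_ssd")
    assert np.isfinite(st)
    assert abs(st - avg) < 60.0
    if np.isfinite(mode):
        assert abs(st - mode) < 80.0
    # exact agreement in the degenerate identical-trial case
    t2 = _trials_from_vectors([400.0], [False, False], [300.0, 300.0])
    b2 = _bursts([
        ("s0", True, 350.0, 450.0, 150.0, 3.0, np.nan, 100.0, 5.0, "premg", False, False),
        ("s1", True, 350.0, 450.0, 150.0, 3.0, np.nan, 100.0, 5.0, "premg", False, False),
    ])
    assert premg_peak_latency(b2, t2, "single_trial") == premg_peak_latency(b2, t2, "mode_ssd") == 150.0


def test_inhibition_function_counting():
    """A step with 2 failed stops, 1 prEMG success and 1 clean success has
    p(press) = 0.5 and p(EMG) = 0.75."""
    trials = _trials_from_vectors([400.0], [True, True, False, False],
                                  [300.0] * 4)
    bursts = _bursts([
        ("s0", True, 350.0, 450.0, 150.0, 3.0, 50.0, 100.0, 5.0, "ustop_emg", False, False),
        ("s1", True, 350.0, 450.0, 150.0, 3.0, 50.0, 100.0, 5.0, "ustop_emg", False, False),
        ("s2", True, 350.0, 450.0, 150.0, 3.0, np.nan, 100.0, 5.0, "premg", False, False),
        ("s3", False, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, "none", False, False),
    ])
    fn = inhibition_functions(trials, bursts)
    assert len(fn) == 1
    assert fn.loc[0, "p_press"] == 0.5
    assert fn.loc[0, "p_emg"] == 0.75


def test_inhibition_function_all_responded_is_one_everywhere():
    ssds = [200.0, 250.0, 250.0, 300.0]
    trials = _trials_from_vectors([400.0], [True] * 4, ssds)
    bursts = _bursts([
        (f"s{i}", True, 350.0, 450.0, 150.0, 3.0, 50.0, 100.0, 5.0, "ustop_emg", False, False)
        for i in range(4)
    ])
    fn = inhibition_functions(trials, bursts)
    assert (fn["p_press"] == 1.0).all()
    assert (fn["p_emg"] == 1.0).all()


def test_p_emg_dominates_p_press_on_simulated_cohort(mini_participant):
    fn = inhibition_functions(mini_participant["trials"], mini_participant["bursts"])
    assert (fn["p_emg"] >= fn["p_press"] - 1e-12).all()


def test_partition_tiles_and_hand_values():
    """p_press=0.5 on goRT {100..1000} gives a fast portion {100..500} with
    mean 300; p_emg=0.8 gives medium {600,700,800} and slow {900,1000}."""
    go_rts = [100.0 * k for k in range(1, 11)]
    trials = _trials_from_vectors(go_rts, [True, False], [300.0, 300.0])
    bursts = _bursts([])
    out = partition_go_distribution(trials, bursts, 0.5, 0.8)
    assert out["counts"] == (5, 3, 2)
    assert sum(out["counts"]) == out["n"]
    assert out["fast_mean"] == pytest.approx(300.0)
    assert out["medium_mean"] == pytest.approx(700.0)
    assert out["slow_mean"] == pytest.approx(950.0)


def test_partition_context_independence_on_race_simulator(mini_participant):
    """Under the independent race with full EMG initiation, unsuccessful
    stop RTs are fast go trials, so the fast-portion mean approximates the
    unsuccessful-stop RT mean."""
    trials = mini_participant["trials"]
    bursts = mini_participant["bursts"]
    stop = trials[trials["trial_type"] == "stop"]
    p_press = (stop["outcome"] == "stop_fail").mean()
    det = bursts.set_index("trial_id")["emg_class"]
    p_emg = np.mean([
        (o == "stop_fail") or (det.get(t) == "premg")
        for t, o in zip(stop["trial_id"], stop["outcome"])
    ])
    out = partition_go_distribution(trials, bursts, p_press, p_emg,
                                    n_subsamples=200,
                                    rng=np.random.default_rng(0))
    assert abs(out["fast_mean"] - out["us_mean"]) < 40.0
    assert 0.0 <= out["frac_fast_ge_us"] <= 1.0


def test_ssd_profile_bounds_and_absent_cells():
    trials = _trials_from_vectors([400.0], [False, False, True],
                                  [250.0, 250.0, 300.0])
    bursts = _bursts([
        ("s0", True, 350.0, 450.0, 200.0, 3.0, np.nan, 100.0, 5.0, "premg", False, False),
        ("s1", False, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, "none", False, False),
        ("s2", True, 350.0, 450.0, 150.0, 3.0, 50.0, 100.0, 5.0, "ustop_emg", False, False),
    ])
    prof = ssd_profiles(trials, bursts)
    assert ((prof["premg_probability"] >= 0) & (prof["premg_probability"] <= 1)).all()
    at_mode = prof[prof["step"] == 0.0].iloc[0]
    assert at_mode["premg_probability"] == 0.5
    off_mode = prof[prof["step"] == 1.0].iloc[0]
    assert off_mode["premg_probability"] == 0.0
    assert np.isnan(off_mode["peak_stop"])


def test_flat_peak_profile_when_peripheral_latency_ssd_independent(mini_participant):
    """The simulator draws the peripheral stop latency independently of the
    SSD, so the stop-locked peak profile is flat up to selection effects."""
    prof = ssd_profiles(mini_participant["trials"], mini_participant["bursts"])
    peaks = prof["peak_stop"].dropna()
    if len(peaks) >= 3:
        assert peaks.max() - peaks.min() < 120.0


def test_single_trial_prepare_transforms():
    trials = _trials_from_vectors([400.0], [False] * 4,
                                  [200.0, 250.0, 300.0, 350.0])
    bursts = _bursts([
        ("s0", True, 300.0, 400.0, 200.0, 3.0, np.nan, 100.0, 1.0, "premg", False, False),
        ("s1", True, 350.0, 450.0, 200.0, 3.0, np.nan, 100.0, 2.0, "premg", False, False),
        ("s2", True, 400.0, 500.0, 200.0, 3.0, np.nan, 100.0, 3.0, "premg", False, False),
        ("s3", True, 450.0, 550.0, 200.0, 3.0, np.nan, 100.0, 4.0, "premg", False, False),
    ])
    out = single_trial_prepare(bursts, trials)
    # onsets exactly linear in SSD -> all residuals zero
    np.testing.assert_allclose(out["onset_resid"], 0.0, atol=1e-9)
    assert out.loc[out["auc"] == 1.0, "log_auc"].iloc[0] == pytest.approx(0.0)


def test_single_trial_prepare_drops_pre_stop_and_outlier():
    trials = _trials_from_vectors(
        [400.0], [False] * 8, [250.0] * 8)
    rows = []
    for i, onset in enumerate([300.0, 310.0, 320.0, 330.0, 340.0, 350.0, 360.0]):
        rows.append((f"s{i}", True, onset, onset + 100, 100.0, 3.0, np.nan,
                     100.0, 5.0, "premg", False, False))
    # one extreme onset beyond Q3 + 2*IQR of {300..360,900}: and one pre-stop peak
    rows.append(("s7", True, 900.0, 1000.0, -10.0, 3.0, np.nan, 100.0, 5.0,
                 "premg", False, True))
    bursts = _bursts(rows)
    out = single_trial_prepare(bursts, trials)
    assert set(out["trial_id"]) == {f"s{i}" for i in range(7)}


def test_peak_latency_variability_formula_and_outlier_flag():
    rows = []
    for pid, peaks in {
        "p1": [150.0, 170.0],
        "p2": [150.0, 150.0, 150.0],
        "p3": [140.0, 160.0],
        "p4": [150.0, 165.0],
        "p5": [100.0, 400.0],  # wildly variable participant
    }.items():
        for j, pk in enumerate(peaks):
            rows.append({"participant": pid, "trial_id": f"{pid}_{j}",
                         "emg_class": "premg", "peak_stop": pk})
    out = peak_latency_variability(pd.DataFrame(rows)).set_index("participant")
    assert out.loc["p1", "peak_sd"] == pytest.approx(np.sqrt(200.0), rel=1e-6)
    assert out.loc["p2", "peak_sd"] == 0.0
    assert bool(out.loc["p5", "outlier"])
    assert not out.loc[["p1", "p2", "p3", "p4"], "outlier"].any()


def test_variability_parameter_recovery():
    """Sample sd of per-participant stop-locked peaks is an unbiased
    estimate of the generating sd (30 ms, 20 trials, many replicates)."""
    rng = np.random.default_rng(5)
    sds = []
    for r in range(300):
        peaks = rng.normal(165.0, 30.0, 20)
        sds.append(np.std(peaks, ddof=1))
    assert np.mean(sds) == pytest.approx(30.0, abs=1.0)


def test_hand_averaging_is_mean_of_hand_means():
    values = pd.Series([100.0, 200.0, 300.0, 400.0, 500.0])
    hands = pd.Series(["left", "left", "left", "left", "right"])
    # left mean 250, right mean 500 -> 375, not the pooled mean 300
    assert hand_averaged(values, hands) == pytest.approx(375.0)


def test_centered_steps_span_limit():
    ssds = [100.0, 150.0, 200.0, 250.0, 250.0, 300.0, 500.0]
    trials = _trials_from_vectors([400.0], [True] * len(ssds), ssds)
    steps = centered_ssd_steps(trials)
    assert np.nanmax(steps) <= 3
    assert steps.isna().sum() == 1  # the 500 ms trial is 5 steps off-mode
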