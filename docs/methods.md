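# Methods

This note documents the models and procedures implemented in `premg`, the
parameters that matter, the synthetic-data generator, and the numerical
choices made where the design was genuinely open. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## The behavioral model

Behavior in the stop signal task is generated and analysed under the
independent horse-race model. On every trial a go finishing time is drawn;
on stop trials a stop finishing time, started at the stop-signal onset,
races it. A response is emitted iff the go process wins
(`go < SSD + stop`), the go process was initiated at all (no *go failure*),
the stop process was actually triggered (otherwise a *trigger failure*
forces a response), and the finishing time falls inside the 1000 ms
response window. The SSD follows the standard one-up/one-down staircase:
+50 ms after a successful stop, −50 ms after a failed one, initial value
250 ms, clamped to [100, 800] ms; it converges to the SSD at which stopping
succeeds half the time.

Finishing times are modelled as truncated-at-1-ms Gaussians. The published
estimates of the task we emulate report only the first two moments of the
(ex-Gaussian-fitted) finishing-time distributions, and the staircase
equilibrium is governed by the median of `go − stop`; a Gaussian keeps the
median at the printed mean, which is the least-assumption choice given the
available information. Participant-level means are jittered (between-subject
sds below), making each simulated participant a draw from the cohort.

### SimConfig defaults (the study conditions)

| parameter | default | meaning |
|---|---|---|
| n_participants / n_go / n_stop | 46 / 684 / 216 | cohort and trial counts (24% stop), 6 blocks |
| go_mean / go_sd | 546 / 114 ms | within-participant go finishing-time distribution |
| stop_mean / stop_sd | 202 / 31 ms | within-participant stop latency distribution |
| between_subject_go_sd | 77 ms | jitter of participant go means |
| between_subject_stop_sd | 21 ms | jitter of participant stop means |
| p_go_failure / p_trigger_failure | 0.016 / 0.013 | go never initiated / stop never triggered |
| p_choice_error | 0.007 | wrong-hand go responses (kept in the SSRT go-RT vector) |
| staircase | 250 / 50 / [100, 800] ms | initial, step, clamp |
| motor_time_mean / sd | 57 / 13 ms | EMG onset → registered button press |
| response_window | 1000 ms | later responses count as omissions |
| trial_spacing / jitter | 2.25 / 0.25 s | go-onset spacing on the recording clock |

`dependence="onset_coupled"` adds `coupling × (onset − expected onset)` to
the peripheral stop latency, reproducing a positive single-trial association
between going and stopping; `independent` (default) is the null model.

## The EMG generative model

The synthetic EMG is the package's own model; the source analyses observe
prEMG but do not define it generatively. Each channel is band-limited
(20–250 Hz) Gaussian noise with RMS `noise_sd` (8 μV). Every trial in which
the go process reached the muscle adds a burst: a carrier (band-limited
noise by default, an 80 Hz tone in `carrier="tone"` validation mode)
multiplied by an envelope rising over `burst_rise` = 52 ms to `burst_amp` =
200 μV and falling linearly over 80 ms.

The rise is concave, `(t/rise)^0.5`: initial motor-unit recruitment is fast
relative to the later build-up. This shape is also what makes the detector's
onset estimate approximately unbiased — the detection threshold delays the
measured crossing while the centered RMS window advances it, and with this
rise the two effects nearly cancel, so the detected motor time (RT − onset)
recovers the configured electromechanical delay. This is a deliberate
calibration of the generator, not of the detector: every detection
parameter keeps its analysis-side value.

prEMG: a successful stop trial whose muscle onset (`go finishing − motor
time`) precedes `SSD + peripheral stop latency` produces a truncated burst
peaking at that moment. The peripheral latency is drawn per trial as
`N(165, 31²)` ms around a per-participant characteristic value
(`N(premg_mean, premg_between_sd²)`, between-sd 21 ms — individual
differences in stopping speed reach the muscle; without this component
split-half reliability of the peak latency would be zero by construction).
Truncated bursts reach the amplitude of the full-burst rise curve at the
truncation point, capped at 0.9 of the full amplitude; accumulations under
6 ms are treated as no muscle output (below that the truncated burst is
indistinguishable from noise at any realistic SNR). Two consequences worth
keeping in mind:

- prEMG frequency is an *emergent* quantity (~10–20% of successful stops
  under the defaults, at the low end of published datasets, which report
  roughly 20–60% depending on response-device mechanics); raising
  `premg_mean` or the motor time raises it.
- the detected prEMG peak-latency mean sits above the generative 165 ms
  because truncation selects trials where the peripheral latency exceeded
  `onset − SSD` — the truncated-distribution bias the empirical literature
  itself notes.

## The analysis chain

Preprocessing follows a fixed, enforced order (filtered → rms →
baseline_normalized → zscored):

1. **Band-pass** 20–250 Hz, order-2 Butterworth. Applied forward–backward
   (zero-phase) by default because a causal filter would systematically
   delay every onset and peak latency; `zero_phase: false` switches to
   causal mode.
2. **Decimation** to 500 Hz *after* filtering, so the 250 Hz edge sitting at
   the new Nyquist is harmless. Rational ratios are handled; upsampling is
   refused.
3. **Epoching** −0.2 to 1.6 s around each go onset (900 samples at 500 Hz,
   sample at t = 0 included), channel chosen by the trial's required hand
   via an explicit channel→hand map (never inferred from labels). Epochs
   exceeding the recording are flagged `edge`.
4. **Baseline rejection**: mean *rectified* filtered amplitude over
   [−0.2, 0) s above 100 μV flags the trial (rectification makes the
   microvolt criterion sign-invariant; whether the original analysis
   rectified is not documented, so this is stated explicitly).
5. **RMS envelope** over a centered 11-sample (±5) window, interpreted at
   the post-decimation rate (~22 ms); windows truncate at epoch edges
   rather than padding with fabricated data.
6. **Baseline normalization**: each trial divided by its own baseline-window
   mean; a zero baseline flags the trial instead of dividing by zero.
7. **Block-wise z-scoring** per (hand, block) over the concatenated
   non-rejected epochs, population sd (divisor N; at ~10⁵ samples per block
   the sample-sd difference is negligible). Rejected trials are transformed
   with the group statistics but contribute nothing to them or to any
   downstream metric.

Burst detection: threshold 1.2 z, *strict* inequality; search window 0 to
1.6 s post-go (restricting detection to post-go samples is a deliberate
narrowing — letting any sample trigger detection would let baseline noise
in). The peak is the windowed argmax, earliest index on ties. The onset
trace walks backwards from the peak until ≥ 8 ms (4 samples at 500 Hz) of
consecutive sub-threshold samples and returns the first supra-threshold
sample after that run; if no such run exists, the window start is returned
with a warning flag. A single burst per epoch is assumed (the global
maximum defines it). The z-threshold is only meaningful when the block used
for z-scoring contains bursts: the bursts inflate the block sd so that
noise epochs stay far below threshold; a block of pure noise would put its
own maxima above 1.2 sd with near-certainty.

Derived per-trial quantities: `motor_time = rt − onset`, `rise_time = peak
− onset`, `auc` = cumulative envelope amplitude from onset to peak
(inclusive), `peak_stop = peak_go − SSD`. Trials whose stop-locked peak is
negative stay in the burst table flagged `pre_stop_peak`; they are dropped
only in the single-trial preparation, where the cleaning belongs.

Metrics conventions, chosen where the source description is silent:

- Integration SSRT rank: `⌈p·n⌉` on the ascending go-RT vector (1-based),
  the consensus-guide convention; p = 0 or 1 leaves the estimate flagged
  undefined.
- Modal SSD ties resolve to the lowest SSD.
- Mode-centered SSD steps use the staircase step (50 ms) and span ±3.
- The mode-SSD latency estimator averages per-trial stop-locked peaks at
  the modal SSD (rather than taking a waveform peak there).
- Go-distribution partitions cut the sorted values at ranks `⌈p_press·n⌉`
  and `⌈p_EMG·n⌉`, so fast/medium/slow tile the distribution exactly; the
  optional subsample mode redraws size-matched subsets and reports the
  fraction of draws preserving each ordering.
- Outlier rules ("beyond two interquartile ranges") are implemented as
  outside [Q1 − 2·IQR, Q3 + 2·IQR] with linear-interpolation quartiles; the
  participant-level variability flag is upper-tail only.
- SSD residualization of onsets is ordinary least squares per participant
  (skipped and flagged below 3 prEMG trials; a constant-SSD participant
  degenerates to mean-centering); AUC is natural-log-transformed.
- Per-participant sds use the sample (n−1) divisor.
- Hand averaging is the mean of per-hand means, so asymmetric trial counts
  cannot silently reweight a participant's summary.

Reliability: per permutation, each participant's trials are split into
random halves (⌊n/2⌋ / ⌈n/2⌉ for odd n), half-means are correlated across
participants (Pearson by default, Spearman via config) and corrected with
`r′ = 2r/(1+r)`; 10,000 permutations by default, summarized by mean, sd and
the 2.5/97.5 percentiles. Corrected values are clipped at −1 (the formula
maps r < −1/3 below −1) and the fraction of negative permutations is
reported rather than truncated away. The titration analysis subsamples
exactly k trials per eligible participant, without replacement, for k from
6 upward until fewer than 3 participants remain.

## What the simulator does and does not emulate

It emulates: staircase dynamics and their equilibrium, go/trigger failures,
choice errors, omissions, realistic burst SNR and timing, truncated prEMG
with its selection bias, individual differences in going and stopping, and
block/hand structure. It does not emulate: baseline muscle-tone drift,
movement artifacts or cross-talk between muscles, ex-Gaussian RT skew,
device-dependent motor times (fixed 57 ms mean), multi-burst epochs, or any
dependence of the central race on the SSD. Passing tests therefore
demonstrate correctness of the pipeline's logic and its recovery of known
ground truth under these idealized conditions — not robustness to every
artifact of real recordings, which is what the baseline-rejection and
outlier rules exist for.

## Problem sizes and tolerances

The test suite exercises the EMG chain on cohorts of 1–6 participants with
150–300 trials, synthesized at 2000 Hz (the synthesizer's default remains
5000 Hz, the acquisition rate it emulates); behavioral-only checks run the
full 46 × 900 design. The acceptance script averages 10 replicate cohorts
of the full design to report the staircase's stop-accuracy and mean-SSD
equilibria with a Monte-Carlo standard error of a few ms (a single
46-participant cohort has ~11 ms between-cohort sd in mean SSD, driven by
the between-subject jitter). Timing-recovery assertions use the
deterministic tone carrier where exactness is claimed (peak within the
12 ms smoothing half-width + one sample) and the stochastic carrier with
mean-bias bounds elsewhere. Floating-point comparisons in round-trip tests
allow 1e-3 μV (float32 storage in the BrainVision writer); analytic
identities are asserted to 1e-9 or tighter.

## Known limitations

- The average-waveform latency estimator shifts epochs by whole samples
  (SSDs are staircase multiples, so this is exact at 500 Hz with 50 ms
  steps, but sub-sample SSDs would round).
- Burst detection assumes one burst per epoch; double responses merge into
  whichever lobe carries the global maximum.
- The BrainVision writer emits IEEE float32 multiplexed data only — it is a
  fixture/export writer, not a general-purpose converter.
- SSRT estimation inherits the integration method's known fragilities
  (go-RT slowing, short-SSD independence violations); the package reports
  the diagnostics but does not correct for them.
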