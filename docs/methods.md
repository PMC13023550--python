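# Methods

## Signal model

A microphone placed just inside a cow's nostril records each exhalation
as a short (~0.4 s) burst of band-limited noise; inhalations are much
quieter and the waveform between breaths is dominated by broadband
background noise. The breathing rhythm is therefore not a property of
the audio waveform itself but of the slow modulation of its energy:
breath bursts recur once per breath period, 0.3–6 s apart for
physiologically plausible rates of 10–200 breaths per minute (bpm).

The extraction pipeline estimates that modulation period:

1. **Band-pass** (4th-order Butterworth, 100–1200 Hz, applied
   forward–backward with `sosfiltfilt`). Zero-phase filtering keeps the
   energy envelope aligned with the annotated event times; the band
   removes low-frequency rumble (movement, wind) and high-frequency
   content that carries little respiratory energy at an 8 kHz sampling
   rate.
2. **Activity trace.** The filtered signal is squared (instantaneous
   energy), low-pass smoothed at 2 Hz (4th-order Butterworth, zero
   phase) and down-sampled to 50 Hz. Squaring rather than rectification
   or an analytic envelope keeps the operator deterministic and cheap;
   after 2 Hz smoothing the three differ only in scale. The 50 Hz trace
   resolves a 0.3 s period (200 bpm) with 15 samples. Filter ringing
   can dip marginally below zero, so the trace is clipped at 0.
3. **Rolling autocorrelation.** Windows of 1.5, 2, 3, 4, 5, 7 and 10 s
   slide over the trace in 1-s hops. Each window is mean-removed and its
   biased autocorrelation normalized by the lag-0 value, making peak
   heights comparable across window lengths. Lags are searched between
   60/rr_max and min(60/rr_min, window/2) seconds — the upper bound
   guarantees at least two full breath cycles per window, so short
   windows report only fast breathing (a 1.5-s window cannot see
   anything slower than 80 bpm) while long windows stabilize slow
   breathing.
4. **Peak selection.** Within the lag range the candidate period is the
   smallest-lag peak whose normalized correlation is ≥ 0.3 and ≥ 0.8 ×
   the range's global maximum. The 0.8 sub-harmonic guard addresses the
   dominant failure mode of autocorrelation rate estimators: the peak at
   twice the true period is often as high as the fundamental, and a
   plain argmax halves the rate. Two numerical refinements matter in
   noise. First, peaks must have prominence ≥ 0.1; without it, noise
   micro-wiggles on the rising flank of the true peak qualify as
   "smallest-lag local maximum" and bias periods short (at 100 bpm this
   alone was worth ~3 bpm of bias). Second, the integer peak lag is
   refined by parabolic interpolation of its two neighbors, clamped to
   the search range so a rate sitting exactly on the 200 bpm boundary
   remains representable; without sub-sample refinement the 50 Hz trace
   quantizes a 0.6-s period to ±3 bpm steps.
5. **Consensus.** Candidates from all windows within ±30 s of each
   60-s report timestamp are pooled; rates outside 10–200 bpm are
   discarded, and if fewer than 3 candidates survive the report point is
   a gap (`valid=False`). Otherwise the estimate is the median of the
   surviving rates. Gaps are never interpolated: a masked period
   (vocalization, loud ambient noise) yields missing data, not a guess.
6. **Rolling-median summary.** For reporting, a centered 600-s median
   over the valid 60-s estimates, marked invalid where fewer than half
   the window's slots are valid.

The chain is a pure function of (audio, configuration): repeated runs
are byte-identical, scaling the audio by any positive constant changes
nothing (normalized autocorrelation), and prepending silence shifts
timestamps without changing rates.

## Parameters

| parameter | default | role |
|---|---|---|
| band_low / band_high | 100 / 1200 Hz | breath-sound analysis band |
| smooth_cutoff | 2 Hz | envelope smoothing; must exceed max breath rate (3.3 Hz at 200 bpm is intentionally *above* this — see limitations) |
| trace_rate | 50 Hz | activity-trace rate; sets period quantization |
| window_sizes | 1.5–10 s (7 values) | autocorrelation windows |
| hop | 1 s | candidate stride |
| rr_min / rr_max | 10 / 200 bpm | plausibility acceptance range |
| min_peak_corr | 0.3 | minimum normalized peak correlation |
| min_candidates | 3 | minimum evidence per report point |
| report_interval / report_hop | 600 / 60 s | rolling-median window and grid |

On the 2 Hz cutoff: at 200 bpm the breathing fundamental (3.3 Hz) is
attenuated but not removed by the 4th-order low-pass, and the
autocorrelation needs only residual periodicity, so fast rates remain
detectable; the default mirrors the standard analysis settings rather
than the theoretical optimum.

## Reference construction from annotations

Manual annotation marks exhalation onsets; consecutive onset times give
inter-breath intervals and instantaneous rates 60/interval. Rates
outside 10–200 bpm are discarded as annotation artifacts. Each interval
is assigned to the nearest 60-s grid slot (slot value = median of its
intervals) — deliberately mirroring how pipeline candidates are bucketed
— and the result receives the *same* 600-s rolling median as the
estimates. Any asymmetric smoothing between estimate and reference would
show up as spurious (dis)agreement; with symmetric treatment the paired
comparison isolates algorithm error. The event *start* is the breath
timestamp, consistent with annotating exhalation onsets.

Agreement statistics are the conventional paired set: MAE, RMSE, bias
(estimate − reference), SD of the signed error (sample, n−1 convention,
so RMSE² = bias² + SD²·(n−1)/n), Pearson r and R² = r². R² is the
squared correlation, not a regression-through-origin coefficient; a
constant series makes r undefined and it is reported as NaN while the
error moments remain defined.

## Synthetic data: what it emulates and what it does not

The generator reproduces the acoustic structure the pipeline relies on:
band-limited noise bursts (default 200–800 Hz, inside the analysis
band) shaped by a raised-cosine envelope of 0.4 s, recurring at
60/rr(t) intervals with multiplicative lognormal timing jitter (CV 5%,
mean-corrected so expected intervals are unbiased), lognormal per-burst
amplitude variation (CV 20%), stationary Gaussian background noise at
15 dB burst-to-background SNR, and optional loud broadband masking
bursts standing in for vocalization. Defaults were chosen as a
plausible clean-but-noisy nostril recording: jitter and amplitude CVs
in the range of resting mammalian breathing variability, and an SNR at
which bursts are clearly audible — the regime the annotated real
recordings represent ("clearly audible respiration sounds").

It does **not** model: spectral structure of real exhalations beyond a
flat band, inhalation sounds, eructation or heartbeat, non-stationary
barn soundscapes, sensor dropouts, or annotation timing error (labels
are exact). Passing the benchmark therefore demonstrates that the
algorithm recovers rates accurately *when its signal model holds*; it
bounds algorithmic error, not performance on real farm audio, where
reference uncertainty and unmodeled noise add error.

The standard benchmark is 10 recordings × 20 min at 8 kHz: eight
constant targets evenly spanning 20–100 bpm plus two slow ramps (30→70
and 90→50 bpm), default noise and jitter, per-recording seeds spawned
deterministically from one master seed. 20-min recordings give ~20
paired 10-min rolling-median observations each (~200 total), enough to
estimate the agreement statistics while keeping a full run around a
minute on one CPU.

## Group aggregation

Per 10-min bin (anchored at midnight), each animal contributes the mean
of its valid estimates; the group median and 25th/75th percentiles are
taken across contributing animals with linear quantile interpolation
(the convention matters at herd size 5: q25 is the blend of the 2nd and
3rd order statistics). A centered 6-h rolling median smooths the group
series; bins where fewer than half the window's bins are populated are
gaps. The across-animal (not pooled-observation) IQR is reported, since
the band describes herd-level variability.

## Numerical choices and degenerate inputs

- Empty or too-short audio yields an empty activity trace (logged), not
  an error; fully silent audio yields an all-gap series.
- A constant activity trace has zero variance after mean removal;
  autocorrelation is undefined and the window emits no candidate.
- Exact-half bucket boundaries round half-up, not half-to-even:
  uniform 1-s breaths on a 1-s grid otherwise alternate slots and
  produce artificial gaps.
- Median of an even count is the mean of the middle pair (numpy
  convention), relied on by the consensus rule.
- WAV quantization uses the symmetric /32768 convention; round trips
  are exact to half an LSB and +1.0 saturates at code 32767.
- Label files with decimal commas are rejected rather than coerced, so
  locale drift in annotation exports fails loudly.

## Known limitations

- Rates near the window-resolvability edges (below ~12 bpm only the
  10-s window can vote, and min_candidates=3 then requires three
  consecutive hops of one window) produce more gaps than mid-range
  rates.
- The consensus median across *all* windows weights window lengths
  implicitly by their candidate counts; no per-window confidence
  weighting is attempted.
- Periodic non-respiratory sounds inside the acceptance band (e.g.,
  rhythmic chewing at breath-like rates) are indistinguishable from
  breathing by design — the pipeline detects envelope periodicity, not
  breath acoustics.
- Offline batch processing only; no streaming operation.
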