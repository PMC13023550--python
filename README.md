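# rrsonic

Respiration-rate extraction from nostril audio recordings of dairy
cattle.

Respiration rate (RR) is a core indicator of health, stress and heat
strain in dairy cows, but it is usually measured by visually counting
flank movements for a minute or two — labor-intensive, observer-
dependent, and blind to everything outside the observation window. A
clip-on nose-ring microphone records breathing sounds continuously at
the nostril instead: every exhalation is an audible burst, and the
breathing rate is the recurrence rate of those bursts. This package
turns such recordings (mono WAV, typically 8 kHz) into breaths-per-
minute time series and provides everything needed to validate and
analyze them: a synthetic breath-audio generator with exact ground
truth, Audacity label-track I/O for manual annotations, agreement
statistics against annotated references, and group-level diurnal
summaries.

## The algorithm

The audio x(t) is band-pass filtered to the breath-sound band
(100–1200 Hz, zero-phase Butterworth), squared, low-pass smoothed at
2 Hz and down-sampled to 50 Hz, giving a nonnegative *respiration
activity trace* e(t) whose peaks are exhalations. For sliding windows
of length w ∈ {1.5, 2, 3, 4, 5, 7, 10} s (hop 1 s), the normalized
autocorrelation of the mean-removed trace,

    ρ(τ) = Σ ē(t) ē(t+τ) / Σ ē(t)²,

is searched over lags τ ∈ [60/RRmax, min(60/RRmin, w/2)]; the smallest
lag that is a prominent local maximum with ρ ≥ 0.3 and ρ ≥ 0.8·max ρ
(a sub-harmonic guard against period doubling) is a candidate breath
period T, refined to sub-sample precision, with candidate rate
RR = 60/T. Every 60 s, candidates from all windows within ±30 s are
pooled, gated to the plausible range 10–200 bpm, and combined by
median; fewer than 3 surviving candidates means a gap (no value is
interpolated — vocalization or noise masking yields missing data). For
reporting, the 60-s series is summarized by a centered 10-min rolling
median.

The pipeline is deterministic signal processing throughout: no learned
components, identical inputs give byte-identical outputs. See
`docs/methods.md` for the full model, parameter table and limitations.

## Worked example

Generate a 20-minute synthetic recording at a constant 42 bpm, extract
RR, and score it against the generated exhalation labels:

```sh
cat > breath.yaml <<'EOF'
duration: 1200.0        # 20 min
rr_profile: 42.0        # breaths per minute
snr_db: 15.0
EOF
rrsonic synth . --spec breath.yaml --seed 7
rrsonic extract rec00.wav rr.csv
rrsonic eval rr.csv rec00.labels.txt metrics.json
```

which prints

```
wrote 1 recording(s) to .
wrote rr.csv (21 rows, 21 valid)
n=20 mae=0.082 rmse=0.100 bias=+0.052 sd=0.088 r=0.5178 r2=0.2681
```

`rr.csv` holds one row per minute — timestamp, estimated rate, validity
flag and the number of autocorrelation candidates behind the estimate:

```
timestamp_s,rr_bpm,valid,n_candidates
0,42.21554047,true,135
60,41.85541305,true,286
120,42.74168471,true,278
```

The estimates sit within a few tenths of a bpm of the 42 bpm target
(MAE 0.08 bpm over the 20 paired 10-min rolling-median values). The
low correlation is expected here and not a defect: on a constant-rate
recording both series are nearly constant, so r measures noise against
noise; it becomes meaningful when rates vary (on the mixed-rate
benchmark below, r > 0.99). Each command also writes a JSON run
manifest (inputs with SHA-256 checksums, effective configuration, seed,
version) so outputs are traceable.

Multi-animal aggregation: `rrsonic group cow1.csv ... cow5.csv
group.csv` bins each animal's series into 10-min means and reports the
across-animal median with the 25th–75th percentile band plus a 6-h
rolling median — the standard view for herd-level diurnal patterns.

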