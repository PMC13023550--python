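"""Deterministic respiration-rate (RR) extraction from nostril audio.

The chain mirrors how breathing manifests acoustically at the nostril:
each exhalation is a short broadband burst, so the breathing rhythm lives
in the slow modulation of audio energy, not in the audio waveform itself.

Stages
------
1. ``bandpass_filter`` — zero-phase Butterworth band-pass (default
   100–1200 Hz) isolates the breath-sound band from low-frequency rumble
   and high-frequency hiss.
2. ``activity_trace`` — squaring ("energy"), 2 Hz low-pass smoothing and
   down-sampling to 50 Hz turn the audio into a nonnegative respiration
   activity trace whose peaks are exhalations.
3. ``window_candidates`` — rolling normalized autocorrelation of the
   trace over several window lengths (1.5–10 s); the first strong
   autocorrelation peak gives a candidate breathing period per window
   position.  Short windows track fast breathing; long windows stabilize
   slow breathing.
4. ``consensus_rr`` — candidates from all window sizes near a report
   timestamp are gated to the physiologically plausible 10–200 bpm range
   and combined by median; too little surviving evidence yields a gap
   (``valid=False``), never an interpolated value.
5. ``summarize_median`` — rolling median over 10-min windows for
   reporting.

Everything is a pure function of (audio, config): identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal

from rrsonic.audio_io import AudioSegment, RRSeries

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZES = (1.5, 2.0, 3.0, 4.0, 5.0, 7.0, 10.0)


class ConfigurationError(ValueError):
    """Raised when a pipeline configuration is internally inconsistent."""


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the RR extraction pipeline.

    Defaults reproduce the standard analysis settings: 100–1200 Hz
    analysis band, 2 Hz envelope smoothing, 50 Hz activity-trace rate,
    autocorrelation windows of 1.5–10 s, a 10–200 bpm acceptance range
    and 10-min rolling-median reporting on a 1-min grid.
    """

    band_low: float = 100.0  # Hz
    band_high: float = 1200.0  # Hz
    smooth_cutoff: float = 2.0  # Hz
    trace_rate: float = 50.0  # Hz
    window_sizes: tuple[float, ...] = DEFAULT_WINDOW_SIZES  # s
    hop: float = 1.0  # s, candidate-window stride
    rr_min: float = 10.0  # bpm
    rr_max: float = 200.0  # bpm
    min_peak_corr: float = 0.3
    min_candidates: int = 3
    report_interval: float = 600.0  # s, summarizing median window
    report_hop: float = 60.0  # s, report grid spacing

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ConfigurationError(
                f"need 0 < band_low < band_high, got ({self.band_low}, {self.band_high})"
            )
        if not (0 < self.smooth_cutoff < self.trace_rate / 2):
            raise ConfigurationError(
                f"smooth_cutoff {self.smooth_cutoff} Hz must lie below "
                f"trace Nyquist {self.trace_rate / 2} Hz"
            )
        if not (0 < self.rr_min < self.rr_max):
            raise ConfigurationError(f"need 0 < rr_min < rr_max, got ({self.rr_min}, {self.rr_max})")
        ws = tuple(float(w) for w in self.window_sizes)
        object.__setattr__(self, "window_sizes", ws)
        if not ws or any(not (1.5 <= w <= 10.0) for w in ws):
            raise ConfigurationError(f"window sizes must lie within [1.5, 10] s, got {ws}")
        if self.hop <= 0 or self.report_hop <= 0 or self.report_interval <= 0:
            raise ConfigurationError("hop, report_hop and report_interval must be positive")
        if self.min_candidates < 1:
            raise ConfigurationError("min_candidates must be >= 1")


@dataclass(frozen=True)
class ActivityTrace:
    """Low-rate nonnegative respiration-activity envelope of a recording."""

    values: np.ndarray
    rate: float  # Hz
    start_time: float = 0.0  # s

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.size and (not np.all(np.isfinite(values)) or np.min(values) < 0):
            raise ValueError("activity trace values must be finite and nonnegative")
        if self.rate <= 0:
            raise ValueError("trace rate must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.values.size / self.rate


@dataclass(frozen=True)
class RRCandidate:
    """One periodicity detection: a breathing-period candidate.

    ``time`` is the center of the analysis window, ``period`` the lag of
    the selected autocorrelation peak (seconds), ``rr = 60/period`` the
    implied rate, and ``peak_corr`` the normalized correlation at the
    peak (confidence, in [-1, 1]).
    """

    time: float
    window_size: float
    period: float
    peak_corr: float

    @property
    def rr(self) -> float:
        return 60.0 / self.period


# ---------------------------------------------------------------------------
# Stage 1: band-pass


def _bandpass_sos(cfg: PipelineConfig, sample_rate: float) -> np.ndarray:
    nyq = sample_rate / 2.0
    if cfg.band_high >= nyq:
        raise ConfigurationError(
            f"band_high {cfg.band_high} Hz requires sample rate > {2 * cfg.band_high} Hz, "
            f"got {sample_rate} Hz"
        )
    return signal.butter(
        4, [cfg.band_low, cfg.band_high], btype="bandpass", fs=sample_rate, output="sos"
    )


def bandpass_filter(audio: AudioSegment, cfg: PipelineConfig) -> AudioSegment:
    """Zero-phase 4th-order Butterworth band-pass of the raw audio.

    Forward-backward application (``sosfiltfilt``) removes group delay so
    envelope timing is unbiased; passband gain is ~1 and the stopband is
    strongly attenuated.  Output length and rate equal the input's.
    """
    sos = _bandpass_sos(cfg, audio.sample_rate)
    if len(audio) == 0:
        return audio
    filtered = signal.sosfiltfilt(sos, audio.samples)
    return replace(audio, samples=filtered)


# ---------------------------------------------------------------------------
# Stage 2: activity trace


def activity_trace(audio: AudioSegment, cfg: PipelineConfig) -> ActivityTrace:
    """Energy envelope of band-passed audio, smoothed and down-sampled.

    The signal is squared (instantaneous energy), low-pass filtered at
    ``smooth_cutoff`` (zero phase) and resampled to ``trace_rate``.
    Filter ringing can dip below zero, so the trace is clipped at 0.
    Output length is ``floor(duration * trace_rate)``.
    """
    n_out = int(math.floor(len(audio) / audio.sample_rate * cfg.trace_rate))
    if n_out < 1:
        logger.info("audio shorter than one trace sample (%d samples); empty trace", len(audio))
        return ActivityTrace(values=np.empty(0), rate=cfg.trace_rate, start_time=audio.start_time)
    energy = audio.samples**2
    sos = signal.butter(4, cfg.smooth_cutoff, btype="lowpass", fs=audio.sample_rate, output="sos")
    smoothed = signal.sosfiltfilt(sos, energy)
    ratio = audio.sample_rate / cfg.trace_rate
    if abs(ratio - round(ratio)) < 1e-9:
        trace = smoothed[:: int(round(ratio))]
    else:
        frac = Fraction(int(round(cfg.trace_rate * 1000)), int(round(audio.sample_rate * 1000)))
        trace = signal.resample_poly(smoothed, frac.numerator, frac.denominator)
    trace = np.clip(trace[:n_out], 0.0, None)
    return ActivityTrace(values=trace, rate=cfg.trace_rate, start_time=audio.start_time)


# ---------------------------------------------------------------------------
# Stage 3: rolling autocorrelation


def _autocorr_normalized(window: np.ndarray) -> np.ndarray | None:
    """Mean-removed, biased autocorrelation normalized by its lag-0 value.

    Returns None for (near-)constant windows, where periodicity is
    undefined after mean removal.
    """
    x = window - window.mean()
    r0 = float(np.dot(x, x))
    if r0 <= 0 or not np.isfinite(r0):
        return None
    n = x.size
    r = signal.fftconvolve(x, x[::-1], mode="full")[n - 1 :]
    return r / r0


def _pick_period(
    r: np.ndarray, lag_min: int, lag_max: int, rate: float, min_peak_corr: float
) -> tuple[float, float] | None:
    """Select the breathing-period lag from a normalized autocorrelation.

    Within ``[lag_min, lag_max]`` samples, take the smallest-lag local
    maximum whose correlation is >= ``min_peak_corr`` and >= 0.8x the
    global maximum in the range (sub-harmonic guard against
    period-doubling).  The integer peak is refined by parabolic
    interpolation of its neighbors.  Returns (period_s, peak_corr) or
    None when no acceptable peak exists.
    """
    lag_max = min(lag_max, r.size - 2)
    if lag_max <= lag_min:
        return None
    global_max = float(np.max(r[lag_min : lag_max + 1]))
    threshold = max(min_peak_corr, 0.8 * global_max)
    # peaks are located on the full autocorrelation so a maximum sitting
    # exactly on a range boundary is still seen; prominence rejects
    # noise micro-wiggles riding on the flank of the true peak, which
    # would otherwise win the smallest-lag rule and bias periods short
    peaks, _ = signal.find_peaks(r, height=threshold, prominence=0.1)
    peaks = peaks[(peaks >= lag_min) & (peaks <= lag_max)]
    if peaks.size == 0:
        return None
    k = int(peaks[0])
    rk = r[k]
    # parabolic vertex through (k-1, k, k+1) for sub-sample lag; the
    # refined lag stays inside the search range so boundary rates remain
    # representable exactly
    denom = r[k - 1] - 2.0 * rk + r[k + 1]
    delta = 0.5 * (r[k - 1] - r[k + 1]) / denom if denom < 0 else 0.0
    lag = float(np.clip(k + delta, max(lag_min, k - 0.5), min(lag_max, k + 0.5)))
    return lag / rate, float(rk)


def window_candidates(
    trace: ActivityTrace, window_size: float, cfg: PipelineConfig
) -> list[RRCandidate]:
    """Rolling-autocorrelation period candidates for one window length.

    The window slides over the trace in steps of ``cfg.hop``.  Periods
    are searched between ``60/rr_max`` and ``min(60/rr_min,
    window_size/2)`` seconds — the upper bound guarantees at least two
    full breath cycles inside the window, so each window length only
    reports rates it can actually resolve.  Window positions without an
    acceptable autocorrelation peak contribute no candidate.
    """
    if window_size not in cfg.window_sizes:
        raise ConfigurationError(
            f"window_size {window_size} s is not one of the configured sizes {cfg.window_sizes}"
        )
    rate = trace.rate
    nwin = int(round(window_size * rate))
    if len(trace) < nwin:
        return []
    lag_min = max(1, int(math.ceil(60.0 / cfg.rr_max * rate)))
    lag_max = int(math.floor(min(60.0 / cfg.rr_min, window_size / 2.0) * rate))
    hop_n = max(1, int(round(cfg.hop * rate)))
    out: list[RRCandidate] = []
    for start in range(0, len(trace) - nwin + 1, hop_n):
        r = _autocorr_normalized(trace.values[start : start + nwin])
        if r is None:
            continue
        picked = _pick_period(r, lag_min, lag_max, rate, cfg.min_peak_corr)
        if picked is None:
            continue
        period, peak_corr = picked
        out.append(
            RRCandidate(
                time=trace.start_time + (start + nwin / 2.0) / rate,
                window_size=window_size,
                period=period,
                peak_corr=peak_corr,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Stage 4: consensus


def consensus_rr(
    candidates: Sequence[RRCandidate], timestamp: float, cfg: PipelineConfig
) -> tuple[float, float, bool, int]:
    """Combine per-window candidates at one report time into one estimate.

    Candidates outside the ``[rr_min, rr_max]`` acceptance range are
    discarded; if fewer than ``min_candidates`` survive, the estimate is
    a gap (``valid=False``).  Otherwise the estimate is the median of the
    surviving candidate rates.  Returns ``(timestamp, rr, valid,
    n_candidates)``; insufficient evidence is a valid=False outcome, not
    an error.
    """
    rates = np.array([c.rr for c in candidates], dtype=np.float64)
    rates = rates[(rates >= cfg.rr_min) & (rates <= cfg.rr_max)]
    if rates.size < cfg.min_candidates:
        return timestamp, np.nan, False, int(rates.size)
    return timestamp, float(np.median(rates)), True, int(rates.size)


# ---------------------------------------------------------------------------
# Stage 5: full chain and summary


def extract_rr(audio: AudioSegment, cfg: PipelineConfig | None = None) -> RRSeries:
    """Run the full RR extraction chain on one recording.

    band-pass -> activity trace -> rolling autocorrelation over all
    configured window sizes -> plausibility-gated median consensus on a
    uniform ``report_hop`` grid.  Deterministic: identical audio and
    config give identical output.
    """
    cfg = cfg or PipelineConfig()
    if len(audio) == 0:
        raise ValueError("cannot extract RR from empty audio")
    filtered = bandpass_filter(audio, cfg)
    trace = activity_trace(filtered, cfg)
    candidates: list[RRCandidate] = []
    for ws in cfg.window_sizes:
        candidates.extend(window_candidates(trace, ws, cfg))

    t0 = audio.start_time
    n_reports = int(math.floor(audio.duration / cfg.report_hop)) + 1
    timestamps = t0 + np.arange(n_reports) * cfg.report_hop
    # bucket candidates by nearest report timestamp (+- report_hop/2)
    buckets: list[list[RRCandidate]] = [[] for _ in range(n_reports)]
    for c in candidates:
        idx = int(math.floor((c.time - t0) / cfg.report_hop + 0.5))
        if 0 <= idx < n_reports:
            buckets[idx].append(c)

    rr = np.full(n_reports, np.nan)
    valid = np.zeros(n_reports, dtype=bool)
    n_cand = np.zeros(n_reports, dtype=np.int64)
    for i, ts in enumerate(timestamps):
        _, rr[i], valid[i], n_cand[i] = consensus_rr(buckets[i], float(ts), cfg)
    n_gaps = int(np.sum(~valid))
    logger.info(
        "extract_rr: %d report points, %d valid, %d gaps, %d raw candidates",
        n_reports, n_reports - n_gaps, n_gaps, len(candidates),
    )
    return RRSeries(timestamps=timestamps, rr=rr, valid=valid, n_candidates=n_cand)


def summarize_median(series: RRSeries, cfg: PipelineConfig | None = None) -> RRSeries:
    """Rolling-median summary of an RR series for reporting.

    A centered window of ``report_interval`` seconds slides over the
    uniform ``report_hop`` grid; the output at each timestamp is the
    median of the *valid* estimates in the window, and is itself a gap
    when fewer than half of the window's grid slots hold valid values.
    """
    cfg = cfg or PipelineConfig()
    n = len(series)
    if n == 0:
        return series
    hop = series.hop
    if n > 1 and not np.isfinite(hop):
        raise ValueError("summarize_median requires a uniform timestamp grid")
    half = cfg.report_interval / 2.0
    rr = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    n_cand = np.zeros(n, dtype=np.int64)
    ts = series.timestamps
    for i in range(n):
        in_win = np.abs(ts - ts[i]) <= half + 1e-9
        vals = series.rr[in_win & series.valid]
        n_slots = int(np.sum(in_win))
        n_cand[i] = vals.size
        if n_slots and vals.size >= 0.5 * n_slots:
            rr[i] = np.median(vals)
            valid[i] = True
    return RRSeries(timestamps=ts.copy(), rr=rr, valid=valid, n_candidates=n_cand)
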