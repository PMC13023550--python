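"""Synthetic nostril breath audio with known ground truth.

Real recordings show each exhalation as a short burst of band-limited
noise riding on broadband background noise; breathing rhythm appears as
the recurrence of these bursts.  The generator reproduces exactly that
structure — and nothing more — so every pipeline stage can be exercised
against exact ground truth without any recorded data:

* exhalation bursts: white noise band-passed to ``breath_band`` and
  shaped by a raised-cosine envelope of ``breath_duration``;
* breath timing: inter-breath intervals of ``60 / rr_profile(t)``
  seconds with multiplicative lognormal jitter (keeps intervals
  positive);
* per-breath amplitude variation (lognormal, mean 1);
* stationary Gaussian background noise at a configurable burst-to-noise
  SNR;
* optional masking events — loud broadband bursts emulating cow
  vocalization — that locally bury the respiratory signal.

Outputs are an :class:`~rrsonic.audio_io.AudioSegment`, an Audacity-style
:class:`~rrsonic.audio_io.LabelTrack` with one ``'b'`` event per breath,
and a ground-truth RR series (60 / actual interval at each breath).  All
randomness flows from the single explicit seed; no global random state
is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import signal

from rrsonic.audio_io import AudioSegment, LabelEvent, LabelTrack, RRSeries

RRProfile = Callable[[float], float]

RR_PROFILE_MIN = 10.0  # bpm, physiological floor for generated profiles
RR_PROFILE_MAX = 200.0  # bpm


@dataclass(frozen=True)
class MaskingEvent:
    """A broadband burst (e.g., vocalization) that masks breathing.

    ``level_db`` is the burst RMS relative to the nominal breath-burst
    RMS, in dB; positive values bury the breath signal.
    """

    start: float  # s
    duration: float  # s
    level_db: float = 20.0


@dataclass(frozen=True)
class SynthSpec:
    """Full description of one synthetic recording."""

    duration: float  # s
    sample_rate: int = 8000  # Hz
    rr_profile: RRProfile | float = 40.0  # bpm, constant or function of time
    breath_duration: float = 0.4  # s
    breath_band: tuple[float, float] = (200.0, 800.0)  # Hz, inside analysis band
    timing_jitter_cv: float = 0.05  # CV of inter-breath intervals
    amplitude_cv: float = 0.2  # CV of per-breath amplitude
    snr_db: float = 15.0  # breath-burst RMS over background RMS; inf = clean
    masking_events: tuple[MaskingEvent, ...] = ()
    seed: int = 0
    subject_id: str | None = None

    def rr_at(self, t: float) -> float:
        """Target respiration rate (bpm) at time ``t`` seconds."""
        profile = self.rr_profile
        return float(profile(t)) if callable(profile) else float(profile)

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        lo, hi = self.breath_band
        if not (0 < lo < hi < self.sample_rate / 2):
            raise ValueError(f"breath_band {self.breath_band} must lie below Nyquist")
        if self.timing_jitter_cv < 0 or self.amplitude_cv < 0:
            raise ValueError("coefficients of variation must be nonnegative")
        rates = [self.rr_at(t) for t in np.linspace(0.0, self.duration, 101)]
        if min(rates) < RR_PROFILE_MIN or max(rates) > RR_PROFILE_MAX:
            raise ValueError(
                f"rr_profile must stay within [{RR_PROFILE_MIN}, {RR_PROFILE_MAX}] bpm, "
                f"got range [{min(rates):.1f}, {max(rates):.1f}]"
            )
        min_interval = 60.0 / max(rates)
        if self.breath_duration >= min_interval:
            raise ValueError(
                f"breath_duration {self.breath_duration} s does not fit the shortest "
                f"inter-breath interval {min_interval:.3f} s"
            )


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative lognormal perturbation with mean 1 and given CV."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def _breath_burst(rng: np.random.Generator, spec: SynthSpec) -> np.ndarray:
    """One unit-RMS exhalation burst: band-limited noise, Hann envelope."""
    n = max(8, int(round(spec.breath_duration * spec.sample_rate)))
    noise = rng.standard_normal(n)
    sos = signal.butter(4, spec.breath_band, btype="bandpass", fs=spec.sample_rate, output="sos")
    shaped = signal.sosfiltfilt(sos, noise) * np.hanning(n)
    rms = float(np.sqrt(np.mean(shaped**2)))
    return shaped / rms if rms > 0 else shaped


def generate_breath_audio(spec: SynthSpec) -> tuple[AudioSegment, LabelTrack, RRSeries]:
    """Synthesize one recording plus its label track and ground-truth RR.

    Breath onsets are placed sequentially: the interval after a breath at
    time ``t`` is ``60 / rr_profile(t)`` multiplied by lognormal jitter.
    The ground-truth series carries ``60 / actual interval`` at each
    interval midpoint.  Fully reproducible from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    n_total = int(round(spec.duration * fs))
    audio = np.zeros(n_total)

    # breath placement
    onsets: list[float] = []
    t = 0.25 * 60.0 / spec.rr_at(0.0)  # lead-in of a quarter interval
    while t + spec.breath_duration <= spec.duration:
        onsets.append(t)
        interval = 60.0 / spec.rr_at(t) * _lognormal_factor(rng, spec.timing_jitter_cv)
        burst = _breath_burst(rng, spec) * _lognormal_factor(rng, spec.amplitude_cv)
        i0 = int(round(t * fs))
        audio[i0 : i0 + burst.size] += burst[: n_total - i0]
        t += interval

    if len(onsets) < 2:
        raise ValueError("spec too short: fewer than two breaths fit the duration")

    # background noise at the requested burst-to-noise SNR
    if np.isfinite(spec.snr_db):
        sigma = 10.0 ** (-spec.snr_db / 20.0)  # nominal burst RMS is 1
        audio += sigma * rng.standard_normal(n_total)

    # masking events (vocalization analogs): loud full-band noise
    for ev in spec.masking_events:
        i0 = max(0, int(round(ev.start * fs)))
        i1 = min(n_total, int(round((ev.start + ev.duration) * fs)))
        if i1 > i0:
            level = 10.0 ** (ev.level_db / 20.0)
            audio[i0:i1] += level * rng.standard_normal(i1 - i0)

    peak = float(np.max(np.abs(audio)))
    if peak > 0:
        audio *= 0.9 / peak

    segment = AudioSegment(
        samples=audio, sample_rate=fs, start_time=0.0, subject_id=spec.subject_id
    )
    track = LabelTrack(
        events=tuple(
            LabelEvent(start=s, end=s + spec.breath_duration, label="b") for s in onsets
        ),
        source=f"synthetic(seed={spec.seed})",
    )
    starts = np.asarray(onsets)
    intervals = np.diff(starts)
    truth = RRSeries(
        timestamps=(starts[:-1] + starts[1:]) / 2.0,
        rr=60.0 / intervals,
        valid=np.ones(intervals.size, dtype=bool),
        n_candidates=np.ones(intervals.size, dtype=np.int64),
    )
    return segment, track, truth


def diurnal_profile(
    low_bpm: float, high_bpm: float, period_h: float = 24.0
) -> RRProfile:
    """Smooth day/night respiration-rate profile.

    Returns a function of time (seconds) tracing a sinusoid with minimum
    ``low_bpm`` at the night phase (03:00 of each cycle) and maximum
    ``high_bpm`` at the day phase (15:00), matching the typical pattern
    of low nocturnal and high early-afternoon rates.  ``period_h``
    compresses the cycle for desk-scale tests.  ``low == high`` yields a
    constant profile.
    """
    if not (RR_PROFILE_MIN <= low_bpm <= high_bpm <= RR_PROFILE_MAX):
        raise ValueError(
            f"need {RR_PROFILE_MIN} <= low <= high <= {RR_PROFILE_MAX}, "
            f"got ({low_bpm}, {high_bpm})"
        )
    if period_h <= 0:
        raise ValueError("period_h must be positive")
    mid = (low_bpm + high_bpm) / 2.0
    amp = (high_bpm - low_bpm) / 2.0
    period_s = period_h * 3600.0
    night_phase = (3.0 / 24.0) * period_s  # trough at 03:00 of the cycle

    def profile(t: float) -> float:
        return mid - amp * math.cos(2.0 * math.pi * (t - night_phase) / period_s)

    return profile


# ---------------------------------------------------------------------------
# Standard benchmark


BENCHMARK_N_RECORDINGS = 10
BENCHMARK_DURATION_S = 1200.0  # 20 min each
BENCHMARK_RR_RANGE = (20.0, 100.0)  # bpm


def _ramp(start_bpm: float, end_bpm: float, duration: float) -> RRProfile:
    def profile(t: float) -> float:
        frac = min(max(t / duration, 0.0), 1.0)
        return start_bpm + (end_bpm - start_bpm) * frac

    return profile


def benchmark_specs(seed: int) -> list[SynthSpec]:
    """Specs of the standard benchmark: 10 x 20-min recordings at 8 kHz.

    Eight constant-rate targets evenly spanning 20–100 bpm plus two slow
    ramps (30→70 and 90→50 bpm over the recording), all with default
    noise and jitter.  Per-recording seeds derive deterministically from
    the master seed.
    """
    children = np.random.SeedSequence(seed).spawn(BENCHMARK_N_RECORDINGS)
    lo, hi = BENCHMARK_RR_RANGE
    profiles: list[RRProfile | float] = [
        float(r) for r in np.linspace(lo, hi, BENCHMARK_N_RECORDINGS - 2)
    ]
    profiles.append(_ramp(30.0, 70.0, BENCHMARK_DURATION_S))
    profiles.append(_ramp(90.0, 50.0, BENCHMARK_DURATION_S))
    return [
        SynthSpec(
            duration=BENCHMARK_DURATION_S,
            rr_profile=profile,
            seed=int(child.generate_state(1)[0] & 0x7FFFFFFF),
            subject_id=f"synthetic-{k:02d}",
        )
        for k, (profile, child) in enumerate(zip(profiles, children))
    ]


def benchmark_suite(seed: int) -> list[tuple[AudioSegment, LabelTrack, RRSeries]]:
    """Generate the full standard benchmark (see :func:`benchmark_specs`)."""
    return [generate_breath_audio(spec) for spec in benchmark_specs(seed)]
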