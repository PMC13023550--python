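"""Readers and writers for the formats the tool touches.

Three external formats are supported:

* mono WAV audio (RIFF/WAVE, integer PCM or IEEE float), the raw output
  of the nostril recorder;
* Audacity label tracks, tab-separated ``start<TAB>end<TAB>label`` lines
  with times in decimal seconds, the format used for manual exhalation
  annotation;
* respiration-rate (RR) series CSV with columns
  ``timestamp_s, rr_bpm, valid, n_candidates``.

All readers validate strictly and never modify the input file.  The
canonical WAV output dialect is 16-bit PCM little-endian mono; readers
additionally accept 24/32-bit PCM and float encodings and normalize
samples to [-1, 1].  Recordings are expected at 8 kHz; other rates are
accepted with a logged warning and processed at their actual rate rather
than resampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.io import wavfile

logger = logging.getLogger(__name__)

#: Acquisition sample rate of the nostril recorder (Hz).
EXPECTED_SAMPLE_RATE = 8000

RR_CSV_COLUMNS = ("timestamp_s", "rr_bpm", "valid", "n_candidates")


class FormatError(ValueError):
    """Raised when a file does not conform to its declared format."""


@dataclass(frozen=True)
class AudioSegment:
    """A uniformly sampled mono pressure-amplitude signal.

    Parameters
    ----------
    samples
        Amplitude values normalized to [-1, 1], finite.
    sample_rate
        Sampling frequency in Hz, positive.
    start_time
        Offset of the first sample in seconds since recording start.
    subject_id
        Optional opaque identifier of the recorded animal.
    """

    samples: np.ndarray
    sample_rate: int
    start_time: float = 0.0
    subject_id: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise FormatError(f"audio must be mono, got {samples.ndim}-d array")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("audio samples must be finite")
        # I/O keeps samples in [-1, 1]; intermediate processing (e.g.
        # zero-phase filtering) may overshoot slightly, so the container
        # itself only requires finiteness
        if not (isinstance(self.sample_rate, (int, np.integer)) and self.sample_rate > 0):
            raise ValueError(f"sample_rate must be a positive integer, got {self.sample_rate!r}")
        if self.start_time < 0:
            raise ValueError("start_time must be >= 0")

    @property
    def duration(self) -> float:
        """Length of the segment in seconds."""
        return self.samples.size / self.sample_rate

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class LabelEvent:
    """One annotated event: ``[start, end]`` seconds plus a text label."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"event end {self.end} precedes start {self.start} (label {self.label!r})"
            )


@dataclass(frozen=True)
class LabelTrack:
    """An ordered track of annotated events (Audacity label-track model).

    Event starts must be strictly increasing; each ``'b'`` event marks one
    audible exhalation in the annotation workflow.
    """

    events: tuple[LabelEvent, ...]
    source: str = "<memory>"

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        starts = [e.start for e in events]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError(f"event starts must be strictly increasing in {self.source}")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[LabelEvent]:
        return iter(self.events)

    def starts(self) -> np.ndarray:
        """Event start times in seconds as a float array."""
        return np.array([e.start for e in self.events], dtype=np.float64)


@dataclass
class RRSeries:
    """Timestamped respiration-rate estimates with validity flags.

    ``rr`` is NaN wherever ``valid`` is False (a gap); every valid value
    is a rate in breaths per minute.  Timestamps are seconds since
    recording start and strictly increasing.
    """

    timestamps: np.ndarray
    rr: np.ndarray
    valid: np.ndarray
    n_candidates: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.rr = np.asarray(self.rr, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.n_candidates is None:
            self.n_candidates = np.zeros(self.timestamps.size, dtype=np.int64)
        self.n_candidates = np.asarray(self.n_candidates, dtype=np.int64)
        n = self.timestamps.size
        if not (self.rr.size == self.valid.size == self.n_candidates.size == n):
            raise ValueError("RRSeries arrays must have equal length")
        if n > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("RRSeries timestamps must be strictly increasing")
        if np.any(self.valid & ~np.isfinite(self.rr)):
            raise ValueError("valid estimates must carry a finite rr value")
        # gaps are canonically NaN
        self.rr = np.where(self.valid, self.rr, np.nan)

    def __len__(self) -> int:
        return self.timestamps.size

    @property
    def hop(self) -> float:
        """Grid spacing in seconds; NaN if the series is not uniform."""
        if len(self) < 2:
            return np.nan
        d = np.diff(self.timestamps)
        return float(d[0]) if np.allclose(d, d[0], rtol=0, atol=1e-6) else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp_s": self.timestamps,
                "rr_bpm": self.rr,
                "valid": self.valid,
                "n_candidates": self.n_candidates,
            }
        )


# ---------------------------------------------------------------------------
# WAV


def read_wav(path: str | Path) -> AudioSegment:
    """Read a mono WAV file and normalize its samples to [-1, 1].

    The sample rate is taken verbatim from the header; no resampling is
    performed.  A warning is logged when the rate differs from the 8 kHz
    the recorder produces.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    FormatError
        For multi-channel audio (the message names the channel count) or
        an unsupported sample encoding.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise FormatError(f"{path}: unsupported WAV encoding ({exc})") from exc
    if data.ndim != 1:
        raise FormatError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    samples = _normalize_pcm(data, path)
    if rate != EXPECTED_SAMPLE_RATE:
        logger.warning(
            "%s: sample rate %d Hz differs from the expected %d Hz; "
            "processing at the actual rate",
            path,
            rate,
            EXPECTED_SAMPLE_RATE,
        )
    return AudioSegment(samples=samples, sample_rate=int(rate))


def _normalize_pcm(data: np.ndarray, path: Path) -> np.ndarray:
    """Map integer/float PCM codes onto [-1, 1] floats."""
    if data.dtype == np.int16:
        return data.astype(np.float64) / 32768.0
    if data.dtype == np.int32:
        # covers 24-bit PCM, which scipy widens into int32
        return data.astype(np.float64) / 2147483648.0
    if data.dtype == np.uint8:
        return (data.astype(np.float64) - 128.0) / 128.0
    if data.dtype in (np.float32, np.float64):
        out = data.astype(np.float64)
        peak = np.max(np.abs(out)) if out.size else 0.0
        if peak > 1.0:
            logger.warning("%s: float samples exceed unit range; rescaling by 1/%g", path, peak)
            out = out / peak
        return out
    raise FormatError(f"{path}: unsupported sample dtype {data.dtype}")


def write_wav(segment: AudioSegment, path: str | Path) -> Path:
    """Write a segment as canonical 16-bit PCM little-endian mono WAV.

    Quantization uses the symmetric /32768 convention of the reader, so
    a round trip is exact to half an LSB; +1.0 saturates at the maximum
    positive code 32767 without wrap-around.
    """
    path = Path(path)
    codes = np.clip(np.rint(segment.samples * 32768.0), -32768, 32767).astype("<i2")
    wavfile.write(str(path), int(segment.sample_rate), codes)
    return path


# ---------------------------------------------------------------------------
# Audacity label tracks


def read_label_track(path: str | Path) -> LabelTrack:
    """Parse an Audacity label track (``start<TAB>end<TAB>label`` lines).

    Times must be decimal seconds with ``.`` as the separator; a decimal
    comma is rejected rather than coerced, so locale drift in annotation
    exports fails loudly.  Events are validated (start <= end, strictly
    increasing starts).  An empty file yields an empty track.
    """
    path = Path(path)
    events: list[LabelEvent] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected start<TAB>end<TAB>label, "
                    f"got {len(parts)} field(s): {line!r}"
                )
            start_s, end_s, label = parts
            if "," in start_s or "," in end_s:
                raise FormatError(
                    f"{path}:{lineno}: decimal comma in time field "
                    f"({start_s!r}, {end_s!r}); use '.' as decimal separator"
                )
            try:
                start, end = float(start_s), float(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparsable time field: {line!r}") from exc
            try:
                events.append(LabelEvent(start=start, end=end, label=label))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    events.sort(key=lambda e: e.start)
    return LabelTrack(events=tuple(events), source=str(path))


def write_label_track(track: LabelTrack, path: str | Path) -> Path:
    """Write an Audacity-compatible label track (times with 6 decimals)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for ev in track.events:
            fh.write(f"{ev.start:.6f}\t{ev.end:.6f}\t{ev.label}\n")
    return path


# ---------------------------------------------------------------------------
# RR series CSV


def write_rr_csv(series: RRSeries, path: str | Path) -> Path:
    """Write an RR series as CSV; gaps become empty ``rr_bpm`` fields."""
    path = Path(path)
    frame = series.to_frame()
    frame["valid"] = np.where(series.valid, "true", "false")
    frame.to_csv(path, index=False, float_format="%.10g", na_rep="")
    return path


def read_rr_csv(path: str | Path) -> RRSeries:
    """Read an RR series CSV written by :func:`write_rr_csv`.

    Raises :class:`FormatError` on unknown or missing columns.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"valid": str})
    extra = set(frame.columns) - set(RR_CSV_COLUMNS)
    missing = set(RR_CSV_COLUMNS) - set(frame.columns)
    if extra or missing:
        raise FormatError(
            f"{path}: RR CSV columns must be exactly {list(RR_CSV_COLUMNS)}; "
            f"unknown={sorted(extra)}, missing={sorted(missing)}"
        )
    valid = frame["valid"].str.strip().str.lower().map({"true": True, "false": False})
    if valid.isna().any():
        bad = frame["valid"][valid.isna()].iloc[0]
        raise FormatError(f"{path}: 'valid' must be true/false, got {bad!r}")
    return RRSeries(
        timestamps=frame["timestamp_s"].to_numpy(dtype=np.float64),
        rr=frame["rr_bpm"].to_numpy(dtype=np.float64),
        valid=valid.to_numpy(dtype=bool),
        n_candidates=frame["n_candidates"].to_numpy(dtype=np.int64),
    )
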