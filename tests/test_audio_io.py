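"""Round-trip and validation behavior of the file readers/writers."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.io import wavfile

from rrsonic.audio_io import (
    AudioSegment,
    FormatError,
    LabelEvent,
    LabelTrack,
    RRSeries,
    read_label_track,
    read_rr_csv,
    read_wav,
    write_label_track,
    write_rr_csv,
    write_wav,
)


class TestWav:
    def test_16bit_mono_8khz(self, tmp_path):
        """A 10-s 16-bit PCM file at 8 kHz yields 80,000 normalized samples."""
        path = tmp_path / "a.wav"
        wavfile.write(str(path), 8000, (np.sin(np.linspace(0, 100, 80_000)) * 20000).astype(np.int16))
        seg = read_wav(path)
        assert len(seg) == 80_000
        assert seg.sample_rate == 8000
        assert np.max(np.abs(seg.samples)) <= 1.0

    def test_all_zero_file_reads_as_exact_zeros(self, tmp_path):
        path = tmp_path / "z.wav"
        wavfile.write(str(path), 8000, np.zeros(8000, dtype=np.int16))
        seg = read_wav(path)
        assert np.all(seg.samples == 0.0)

    def test_round_trip_within_one_quantization_step(self, tmp_path, rng):
        seg = AudioSegment(samples=rng.uniform(-0.99, 0.99, 5000), sample_rate=8000)
        back = read_wav(write_wav(seg, tmp_path / "r.wav"))
        assert back.sample_rate == 8000
        assert np.max(np.abs(back.samples - seg.samples)) <= 1.0 / 32768

    def test_write_zeros_one_second(self, tmp_path):
        path = write_wav(AudioSegment(samples=np.zeros(8000), sample_rate=8000), tmp_path / "z.wav")
        rate, data = wavfile.read(str(path))
        assert (rate, data.size, data.dtype) == (8000, 8000, np.int16)
        assert np.all(data == 0)

    def test_full_scale_sample_maps_to_max_positive_code(self, tmp_path):
        seg = AudioSegment(samples=np.array([1.0, -1.0, 0.0]), sample_rate=8000)
        write_wav(seg, tmp_path / "fs.wav")
        _, data = wavfile.read(str(tmp_path / "fs.wav"))
        assert data[0] == 32767  # saturates, no wrap-around
        assert data[1] == -32768

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_wav(tmp_path / "nope.wav")

    def test_stereo_rejected_naming_channel_count(self, tmp_path):
        path = tmp_path / "st.wav"
        wavfile.write(str(path), 8000, np.zeros((100, 2), dtype=np.int16))
        with pytest.raises(FormatError, match="2 channels"):
            read_wav(path)

    def test_float32_and_int32_normalized(self, tmp_path):
        p1, p2 = tmp_path / "f.wav", tmp_path / "i.wav"
        wavfile.write(str(p1), 8000, np.linspace(-1, 1, 100, dtype=np.float32))
        wavfile.write(str(p2), 8000, (np.linspace(-1, 1, 100) * 2**30).astype(np.int32))
        for p in (p1, p2):
            seg = read_wav(p)
            assert np.max(np.abs(seg.samples)) <= 1.0

    def test_non_8khz_rate_warns_but_is_kept(self, tmp_path, caplog):
        path = tmp_path / "r44.wav"
        wavfile.write(str(path), 44100, np.zeros(100, dtype=np.int16))
        with caplog.at_level(logging.WARNING, logger="rrsonic.audio_io"):
            seg = read_wav(path)
        assert seg.sample_rate == 44100
        assert any("8000" in r.message for r in caplog.records)


class TestLabelTrack:
    def test_two_breath_events(self, tmp_path):
        path = tmp_path / "l.txt"
        path.write_text("1.20\t1.55\tb\n2.10\t2.48\tb\n")
        track = read_label_track(path)
        assert len(track) == 2
        assert all(e.label == "b" for e in track)
        assert track.events[0].start == pytest.approx(1.20)

    def test_empty_file_empty_track(self, tmp_path):
        path = tmp_path / "e.txt"
        path.write_text("")
        assert len(read_label_track(path)) == 0

    def test_empty_track_writes_empty_file(self, tmp_path):
        path = write_label_track(LabelTrack(events=()), tmp_path / "e.txt")
        assert path.read_text() == ""

    def test_single_event_formatting(self, tmp_path):
        track = LabelTrack(events=(LabelEvent(0.5, 0.9, "b"),))
        path = write_label_track(track, tmp_path / "one.txt")
        assert path.read_text() == "0.500000\t0.900000\tb\n"

    def test_malformed_line_cites_line_number(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("1.0\t1.2\tb\nnot a line\n")
        with pytest.raises(FormatError, match=":2:"):
            read_label_track(path)

    def test_end_before_start_rejected(self, tmp_path):
        path = tmp_path / "rev.txt"
        path.write_text("2.0\t1.0\tb\n")
        with pytest.raises(FormatError, match=":1:"):
            read_label_track(path)

    def test_decimal_comma_rejected(self, tmp_path):
        path = tmp_path / "comma.txt"
        path.write_text("1,20\t1,55\tb\n")
        with pytest.raises(FormatError, match="decimal comma"):
            read_label_track(path)

    @settings(derandomize=True, max_examples=25)
    @given(
        st.lists(
            st.tuples(st.floats(0, 1e4), st.floats(0, 2.0), st.text(
                alphabet=st.characters(blacklist_characters="\t\n\r", codec="ascii"),
                min_size=1, max_size=8)),
            max_size=50,
        )
    )
    def test_round_trip_identity(self, tmp_path_factory, raw):
        """Write-then-read is the identity on event lists (to 1 us)."""
        starts = sorted({round(s, 6) for s, _, _ in raw})
        events = tuple(
            LabelEvent(s, round(s + d, 6), lab.strip() or "b")
            for s, (_, d, lab) in zip(starts, raw)
        )
        track = LabelTrack(events=events)
        path = tmp_path_factory.mktemp("lt") / "t.txt"
        back = read_label_track(write_label_track(track, path))
        assert len(back) == len(track)
        for a, b in zip(track, back):
            assert a.start == pytest.approx(b.start, abs=1e-6)
            assert a.end == pytest.approx(b.end, abs=1e-6)
            assert a.label == b.label


class TestRRCsv:
    def _series(self, rng, n=1000):
        valid = rng.random(n) > 0.2
        rr = np.where(valid, rng.uniform(10, 200, n), np.nan)
        return RRSeries(
            timestamps=np.arange(n) * 60.0,
            rr=rr,
            valid=valid,
            n_candidates=rng.integers(0, 400, n),
        )

    def test_empty_series_header_only(self, tmp_path):
        series = RRSeries(timestamps=[], rr=[], valid=[])
        path = write_rr_csv(series, tmp_path / "e.csv")
        assert path.read_text().strip() == "timestamp_s,rr_bpm,valid,n_candidates"
        assert len(read_rr_csv(path)) == 0

    def test_gap_row_round_trips(self, tmp_path):
        series = RRSeries(timestamps=[0.0, 60.0], rr=[50.0, np.nan], valid=[True, False])
        back = read_rr_csv(write_rr_csv(series, tmp_path / "g.csv"))
        assert back.valid.tolist() == [True, False]
        assert np.isnan(back.rr[1])

    def test_thousand_row_round_trip_identity(self, tmp_path, rng):
        series = self._series(rng)
        back = read_rr_csv(write_rr_csv(series, tmp_path / "s.csv"))
        np.testing.assert_allclose(back.timestamps, series.timestamps)
        np.testing.assert_allclose(back.rr, series.rr, rtol=1e-9)
        assert np.array_equal(back.valid, series.valid)
        assert np.array_equal(back.n_candidates, series.n_candidates)

    def test_unknown_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("timestamp_s,rr_bpm,valid,n_candidates,extra\n0,50,true,3,1\n")
        with pytest.raises(FormatError, match="extra"):
            read_rr_csv(path)


class TestContainers:
    def test_audio_segment_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            AudioSegment(samples=np.array([np.nan]), sample_rate=8000)
        with pytest.raises(ValueError):
            AudioSegment(samples=np.array([np.inf]), sample_rate=8000)

    def test_label_track_rejects_non_increasing_starts(self):
        with pytest.raises(ValueError):
            LabelTrack(events=(LabelEvent(1.0, 1.2, "b"), LabelEvent(1.0, 1.3, "b")))

    def test_rr_series_rejects_valid_nan(self):
        with pytest.raises(ValueError):
            RRSeries(timestamps=[0.0], rr=[np.nan], valid=[True])
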