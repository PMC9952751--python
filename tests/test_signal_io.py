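"""Record ingestion, windowing arithmetic, label attachment and round trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgvitals.signal_io import (PPGRecord, PPGSegment, ReferenceSeries,
                                 SegmentSet, attach_labels, quality_screen,
                                 read_record, read_segments, segment_record,
                                 write_segments)


def _record(duration_s=480.0, fs=125.0, rr=None, spo2=None, ref_t=None):
    n = int(duration_s * fs)
    rng = np.random.default_rng(0)
    ref = None
    if ref_t is not None:
        ref = ReferenceSeries(np.asarray(ref_t, float),
                              rr=None if rr is None else np.asarray(rr, float),
                              spo2=None if spo2 is None else np.asarray(spo2, float))
    return PPGRecord(rng.normal(size=n), fs, record_id="r0", reference=ref)


class TestRecordValidation:
    def test_csv_record_duration_and_fs_from_time_column(self, tmp_path):
        fs = 125.0
        n = 60000
        t = np.arange(n) / fs
        pd.DataFrame({"Time [s]": t, "PLETH": np.sin(t)}).to_csv(
            tmp_path / "sig.csv", index=False)
        rec = read_record(tmp_path / "sig.csv", "csv")
        assert rec.samples.size == n
        assert rec.duration == pytest.approx(480.0)
        assert rec.fs == pytest.approx(125.0, rel=1e-6)

    def test_csv_with_nan_sample_names_offending_row(self, tmp_path):
        x = np.ones(100)
        x[37] = np.nan
        pd.DataFrame({"Time [s]": np.arange(100) / 10, "PLETH": x}).to_csv(
            tmp_path / "bad.csv", index=False)
        with pytest.raises(ValueError, match="37"):
            read_record(tmp_path / "bad.csv", "csv")

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_record(tmp_path / "nope.csv", "csv")

    def test_fs_absent_and_not_configured_rejected(self, tmp_path):
        pd.DataFrame({"PLETH": np.ones(50)}).to_csv(tmp_path / "noT.csv", index=False)
        with pytest.raises(ValueError, match="sampling frequency"):
            read_record(tmp_path / "noT.csv", "csv")
        rec = read_record(tmp_path / "noT.csv", "csv", fs=50.0)
        assert rec.fs == 50.0

    def test_nonpositive_fs_rejected(self):
        with pytest.raises(ValueError):
            PPGRecord(np.ones(10), fs=0.0)

    def test_reference_timestamps_must_increase(self):
        with pytest.raises(ValueError):
            ReferenceSeries(np.array([0.0, 2.0, 1.0]), rr=np.array([10.0, 11, 12]))


class TestWfdbReader:
    def test_format16_pleth_channel(self, tmp_path):
        # write a two-channel format-16 record: PLETH and a dummy channel
        fs, n = 125, 1250
        pleth = (500 * np.sin(2 * np.pi * 1.2 * np.arange(n) / fs)).astype("<i2")
        other = np.arange(n, dtype="<i2")
        interleaved = np.empty(2 * n, dtype="<i2")
        interleaved[0::2], interleaved[1::2] = pleth, other
        (tmp_path / "rec0.dat").write_bytes(interleaved.tobytes())
        (tmp_path / "rec0.hea").write_text(
            f"rec0 2 {fs} {n}\n"
            "rec0.dat 16 1000(0)/NU 12 0 0 0 0 PLETH\n"
            "rec0.dat 16 1/mV 12 0 0 0 0 II\n")
        rec = read_record(tmp_path / "rec0", "wfdb")
        assert rec.fs == fs
        assert rec.samples.size == n
        # gain 1000, baseline 0 -> amplitudes scaled back
        assert np.allclose(rec.samples, pleth / 1000.0)

    def test_no_pleth_channel_is_an_error(self, tmp_path):
        (tmp_path / "r.dat").write_bytes(np.zeros(10, dtype="<i2").tobytes())
        (tmp_path / "r.hea").write_text("r 1 125 10\nr.dat 16 1/mV 12 0 0 0 0 II\n")
        with pytest.raises(ValueError, match="PLETH"):
            read_record(tmp_path / "r", "wfdb")


class TestSegmentation:
    @pytest.mark.parametrize("duration,expect", [(480.0, 29), (32.0, 1), (31.0, 0)])
    def test_window_counts(self, duration, expect):
        segs = segment_record(_record(duration), 32.0, 0.5)
        assert len(segs) == expect

    def test_segment_length_is_exact(self):
        segs = segment_record(_record(480.0), 32.0, 0.5)
        assert all(s.samples.size == 4000 for s in segs)

    def test_start_time_step(self):
        segs = segment_record(_record(480.0), 32.0, 0.5)
        steps = np.diff([s.start_time for s in segs])
        assert np.allclose(steps, 16.0)

    @given(duration=st.floats(1.0, 300.0), window=st.floats(2.0, 64.0),
           overlap=st.floats(0.0, 0.9))
    @settings(max_examples=60, deadline=None)
    def test_count_closed_form(self, duration, window, overlap):
        """Counts follow floor((T - w)/step) + 1 for any (T, w, overlap)."""
        fs = 25.0
        rec = PPGRecord(np.zeros(int(duration * fs)) + 1.0, fs)
        segs = segment_record(rec, window, overlap)
        nwin = int(round(window * fs))
        nstep = int(round(window * (1 - overlap) * fs))
        if nstep < 1:
            return
        n = rec.samples.size
        expect = 0 if n < nwin else (n - nwin) // nstep + 1
        assert len(segs) == expect

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            segment_record(_record(64.0), 32.0, 1.0)


class TestLabels:
    def test_constant_reference_gives_constant_labels(self):
        rec = _record(96.0, ref_t=np.arange(96.0), rr=np.full(96, 15.0))
        segs = attach_labels(segment_record(rec), rec)
        assert all(s.rr_label == pytest.approx(15.0) for s in segs)

    def test_mean_of_in_window_values(self):
        rec = _record(32.0, ref_t=[5.0, 20.0], rr=[10.0, 20.0])
        segs = attach_labels(segment_record(rec), rec)
        assert segs[0].rr_label == pytest.approx(15.0)

    def test_median_and_midpoint_rules(self):
        rec = _record(32.0, ref_t=[1.0, 15.0, 30.0], rr=[10.0, 12.0, 26.0])
        med = attach_labels(segment_record(rec), rec, rule="median")
        assert med[0].rr_label == pytest.approx(12.0)
        mid = attach_labels(segment_record(rec), rec, rule="midpoint")
        assert mid[0].rr_label == pytest.approx(12.0)  # 15 s is nearest 16 s

    def test_no_in_window_values_flags_unlabeled(self):
        rec = _record(96.0, ref_t=[40.0], spo2=[97.0])
        segs = attach_labels(segment_record(rec), rec)
        # window [0, 32) has no reference points
        assert segs[0].spo2_label is None and segs[0].unlabeled_spo2
        assert segs[1].spo2_label == pytest.approx(97.0)

    def test_empty_reference_warns_and_unlabels_all(self):
        rec = _record(64.0)
        with pytest.warns(UserWarning, match="empty reference"):
            segs = attach_labels(segment_record(rec), rec)
        assert all(s.rr_label is None for s in segs)


class TestInterchange:
    def test_round_trip_bit_exact(self, tmp_path, small_corpus):
        segments, _ = small_corpus
        subset = SegmentSet(segments.segments[:5], provenance=segments.provenance)
        write_segments(subset, tmp_path / "seg.csv")
        back = read_segments(tmp_path / "seg.csv")
        assert len(back) == 5
        for a, b in zip(subset, back):
            assert np.array_equal(a.samples, b.samples)
            assert a.rr_label == b.rr_label and a.spo2_label == b.spo2_label
            assert a.record_id == b.record_id and a.start_time == b.start_time

    def test_quality_screen_drops_flat_and_clipped(self):
        good = PPGSegment(np.sin(np.arange(400) / 10.0), 12.5)
        flat = PPGSegment(np.full(400, 3.2), 12.5)
        clipped = PPGSegment(np.clip(np.sin(np.arange(400) / 10.0), -0.2, 0.2), 12.5)
        out = quality_screen(SegmentSet([good, flat, clipped]))
        assert len(out) == 1
        assert out[0] is good
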