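import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hierbeat import (
    beats_from_recording,
    compute_rr_features,
    load_recording,
    map_symbol_to_aami,
    normalize_beat,
    segment_beat,
    simulate_recording,
    write_recording,
)
from hierbeat.config import DatasetSplit, load_config
from hierbeat.errors import (
    BeatBoundaryError,
    InvalidBeatError,
    NotABeatError,
    RecordingError,
)


class TestSegmentBeat:
    def test_window_is_100_before_through_99_after(self):
        signal = np.arange(1000.0)
        window = segment_beat(signal, 500)
        assert len(window) == 200
        np.testing.assert_array_equal(window, np.arange(400.0, 600.0))

    @pytest.mark.parametrize("r_sample", [50, 901, 0, 999])
    def test_window_outside_signal_raises(self, r_sample):
        with pytest.raises(BeatBoundaryError):
            segment_beat(np.zeros(1000), r_sample)

    def test_window_end_boundary_is_exact(self):
        # r=900 in a 1000-sample signal occupies [800, 1000) and just fits;
        # one sample later exceeds the signal
        assert len(segment_beat(np.zeros(1000), 900)) == 200
        with pytest.raises(BeatBoundaryError):
            segment_beat(np.zeros(1000), 901)

    def test_custom_window_length(self):
        window = segment_beat(np.arange(100.0), 50, window_len=10, pre_samples=5)
        np.testing.assert_array_equal(window, np.arange(45.0, 55.0))


class TestNormalizeBeat:
    def test_closed_form_three_samples(self):
        # population sd of [1,2,3] is sqrt(2/3)
        out = normalize_beat([1.0, 2.0, 3.0])
        np.testing.assert_allclose(out, np.array([-1, 0, 1]) * np.sqrt(1.5), atol=1e-12)
        assert abs(out.mean()) < 1e-9
        assert abs(out.std() - 1) < 1e-9

    @given(
        arrays(
            np.float64,
            st.integers(5, 80),
            elements=st.floats(-50, 50, allow_nan=False),
        ).filter(lambda x: x.std() > 1e-6)
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_standardized(self, x):
        once = normalize_beat(x)
        assert abs(once.mean()) < 1e-9
        assert abs(once.std() - 1.0) < 1e-9
        np.testing.assert_allclose(normalize_beat(once), once, atol=1e-9)

    def test_flat_window_invalid(self):
        with pytest.raises(InvalidBeatError):
            normalize_beat([5.0, 5.0, 5.0])


class TestSymbolMap:
    @pytest.mark.parametrize(
        "symbol,expected",
        [
            ("V", "V"),  # premature ventricular contraction
            ("E", "V"),
            ("A", "S"),  # atrial premature
            ("a", "S"),
            ("J", "S"),
            ("N", "N"),
            ("L", "N"),
            ("R", "N"),
            ("F", "F"),
            ("/", "Q"),
            ("f", "Q"),
        ],
    )
    def test_aami_mapping(self, symbol, expected):
        assert map_symbol_to_aami(symbol) == expected

    def test_unknown_beat_code_falls_to_q(self):
        assert map_symbol_to_aami("Z") == "Q"

    @pytest.mark.parametrize("symbol", ["+", "~", "|", "[", "]", "!", "x"])
    def test_non_beat_codes_rejected(self, symbol):
        with pytest.raises(NotABeatError):
            map_symbol_to_aami(symbol)


class TestRRFeatures:
    def test_uniform_rhythm(self):
        rr_prev, rr_ratio = compute_rr_features([0.0, 1.0, 2.0, 3.0])
        np.testing.assert_allclose(rr_prev[1:], [1, 1, 1])
        np.testing.assert_allclose(rr_ratio[1:], [1, 1, 1])
        assert np.isnan(rr_prev[0]) and np.isnan(rr_ratio[0])

    def test_irregular_rhythm_arithmetic(self):
        rr_prev, rr_ratio = compute_rr_features([0.0, 1.0, 1.5, 2.5])
        np.testing.assert_allclose(rr_prev[1:], [1.0, 0.5, 1.0])
        np.testing.assert_allclose(rr_ratio[1:], [1.2, 0.6, 1.2])

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_ratio_invariant_under_time_dilation(self, k):
        times = np.array([0.0, 0.8, 1.5, 2.1, 3.4])
        _, base = compute_rr_features(times)
        _, scaled = compute_rr_features(times * k)
        np.testing.assert_allclose(scaled[1:], base[1:], rtol=1e-9)

    def test_single_beat_errors(self):
        with pytest.raises(ValueError):
            compute_rr_features([1.0])


class TestRecordingIO:
    def test_synthetic_recording_round_trips(self, tmp_path):
        rec = simulate_recording(n_beats=30, record_id="901", seed=5)
        write_recording(rec, tmp_path)
        back = load_recording(tmp_path, "901")
        assert back.record_id == rec.record_id
        assert back.leads == rec.leads
        # signal values survive the fixed-precision CSV round trip
        np.testing.assert_allclose(back.signals["A"], rec.signals["A"], atol=1e-6)
        assert [a.r_sample for a in back.annotations] == [
            a.r_sample for a in rec.annotations
        ]
        assert [a.symbol for a in back.annotations] == [
            a.symbol for a in rec.annotations
        ]

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(RecordingError):
            load_recording(tmp_path, "nope")

    def test_sampling_rate_mismatch_errors(self, tmp_path):
        rec = simulate_recording(n_beats=10, record_id="902", seed=5)
        write_recording(rec, tmp_path)
        with pytest.raises(RecordingError):
            load_recording(tmp_path, "902", expected_sampling_rate=250.0)

    def test_annotation_outside_signal_dropped_with_warning(self, tmp_path):
        rec = simulate_recording(n_beats=10, record_id="903", seed=5)
        write_recording(rec, tmp_path)
        ann_path = tmp_path / "903.annotations.csv"
        ann_path.write_text(ann_path.read_text() + "999999,N\n")
        with pytest.warns(UserWarning, match="outside"):
            back = load_recording(tmp_path, "903")
        assert len(back.annotations) == len(rec.annotations)


class TestBeatExtraction:
    def test_beat_count_conservation(self):
        rec = simulate_recording(n_beats=120, seed=7)
        beats = beats_from_recording(rec)
        c = beats.drop_counts
        assert (
            c["retained"] + c["non_beat"] + c["first_beat"] + c["boundary"] + c["flat"]
            == len(rec.annotations)
        )
        assert c["retained"] == len(beats)

    def test_retained_beats_are_normalized_200_sample_windows(self):
        rec = simulate_recording(n_beats=60, seed=8)
        beats = beats_from_recording(rec)
        for lead in ("A", "B"):
            w = beats.lead_windows[lead]
            assert w.shape == (len(beats), 200)
            np.testing.assert_allclose(w.mean(axis=1), 0, atol=1e-9)
            np.testing.assert_allclose(w.std(axis=1), 1, atol=1e-9)
        assert (beats.rr_prev_s > 0).all()
        assert (beats.rr_ratio > 0).all()

    def test_edge_beat_dropped_not_padded(self):
        rec = simulate_recording(n_beats=40, seed=9, margin_s=0.1)
        # 0.1 s margin < 100 samples / 360 Hz, so the outermost beats cannot
        # fit a full window
        beats = beats_from_recording(rec)
        assert beats.drop_counts["boundary"] >= 1
        assert all(w.shape[1] == 200 for w in beats.lead_windows.values())


class TestDatasetSplit:
    def test_reference_split_is_disjoint_and_excludes_paced(self):
        split = DatasetSplit.from_config(load_config())
        assert len(split.ds1_records) == 22
        assert len(split.ds2_records) == 22
        assert not set(split.ds1_records) & set(split.ds2_records)
        assert set(split.excluded_records) == {"102", "104", "107", "217"}
        assert not (set(split.ds1_records) | set(split.ds2_records)) & set(
            split.excluded_records
        )

    def test_overlapping_split_rejected(self):
        with pytest.raises(ValueError):
            DatasetSplit(("1", "2"), ("2", "3"))
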