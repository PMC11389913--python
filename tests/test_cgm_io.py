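import numpy as np
import pytest

from gluforecast.cgm_io import (
    CsvDialect,
    GlucoseSeries,
    pooled_summary,
    read_cgm_csv,
    regularize,
    summarize,
    write_cgm_csv,
)
from gluforecast.errors import (
    DuplicateTimestampError,
    EmptyInputError,
    FormatError,
    InsufficientDataError,
    ParameterError,
)

from conftest import T0, STEP5, regular_series


class TestReadWrite:
    def test_three_row_file_roundtrip_exact(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text(
            "patient_id,timestamp,glucose_mmol_l,calibration_bg_mmol_l\n"
            "P1,2022-03-01T00:00:00,5.5,\n"
            "P1,2022-03-01T00:05:00,6.25,6.1\n"
            "P1,2022-03-01T00:10:00,7.75,\n"
        )
        s = read_cgm_csv(path)
        assert len(s) == 3
        np.testing.assert_array_equal(s.glucose, [5.5, 6.25, 7.75])
        assert s.patient_id == "P1"
        assert np.isnan(s.calibration_bg[0]) and s.calibration_bg[1] == 6.1

    def test_duplicate_timestamp_raises_naming_instant(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "patient_id,timestamp,glucose_mmol_l\n"
            "P1,2022-03-01T00:00:00,5.0\n"
            "P1,2022-03-01T00:00:00,5.1\n"
        )
        with pytest.raises(DuplicateTimestampError, match="2022-03-01T00:00:00"):
            read_cgm_csv(path)

    def test_one_bad_glucose_cell_dropped_with_warning(self, tmp_path, caplog):
        rows = [
            f"P1,2022-03-01T00:{5*i:02d}:00,{5.0+i}" for i in range(10)
        ]
        rows[4] = "P1,2022-03-01T00:20:00,oops"
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,timestamp,glucose_mmol_l\n" + "\n".join(rows))
        with caplog.at_level("WARNING"):
            s = read_cgm_csv(path)
        assert len(s) == 9
        assert any("dropped 1" in r.message for r in caplog.records)

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("patient_id,when,glucose_mmol_l\nP1,2022-01-01,5\n")
        with pytest.raises(FormatError, match="timestamp"):
            read_cgm_csv(path)

    def test_all_rows_invalid_is_empty_input_error(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("patient_id,timestamp,glucose_mmol_l\nP1,2022-01-01,x\n")
        with pytest.raises(EmptyInputError):
            read_cgm_csv(path)

    def test_roundtrip_576_points(self, tmp_path):
        rng = np.random.default_rng(0)
        cal = np.full(576, np.nan)
        cal[[10, 200]] = [7.0, 8.5]
        s = regular_series(rng.uniform(3, 18, 576).round(4), cal=cal)
        path = write_cgm_csv(s, tmp_path / "rt.csv")
        back = read_cgm_csv(path)
        np.testing.assert_array_equal(back.timestamps, s.timestamps)
        np.testing.assert_allclose(back.glucose, s.glucose, atol=5e-5)
        np.testing.assert_allclose(
            back.calibration_bg[[10, 200]], [7.0, 8.5]
        )
        assert np.isnan(back.calibration_bg).sum() == 574

    def test_write_empty_series_refused(self, tmp_path):
        s = regular_series([5.0, 6.0])
        s.timestamps = s.timestamps[:0]
        s.glucose = s.glucose[:0]
        s.calibration_bg = s.calibration_bg[:0]
        with pytest.raises(EmptyInputError):
            write_cgm_csv(s, tmp_path / "e.csv")

    def test_mgdl_units_converted(self, tmp_path):
        path = tmp_path / "mg.csv"
        path.write_text(
            "patient_id,timestamp,glucose\n"
            "P1,2022-03-01T00:00:00,180.16\n"
            "P1,2022-03-01T00:05:00,90.08\n"
        )
        s = read_cgm_csv(
            path, CsvDialect(glucose_col="glucose", units="mg/dL",
                             calibration_col=None)
        )
        np.testing.assert_allclose(s.glucose, [10.0, 5.0])


class TestSeriesInvariants:
    def test_nonpositive_glucose_rejected(self):
        with pytest.raises(ParameterError):
            regular_series([5.0, 0.0, 6.0])

    def test_unsorted_timestamps_rejected(self):
        ts = np.array(
            ["2022-03-01T00:05:00", "2022-03-01T00:00:00"], dtype="datetime64[s]"
        )
        with pytest.raises(ParameterError):
            GlucoseSeries("P1", ts, np.array([5.0, 6.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            GlucoseSeries(
                "P1",
                np.array(["2022-03-01T00:00:00"], dtype="datetime64[s]"),
                np.array([5.0, 6.0]),
            )


class TestRegularize:
    def test_missing_slot_filled_with_linear_midpoint(self):
        ts = T0 + np.array([0, 1, 3], dtype="int64") * STEP5
        s = GlucoseSeries("P1", ts, np.array([4.0, 6.0, 10.0]))
        segs = regularize(s, 5, 15)
        assert len(segs) == 1
        np.testing.assert_allclose(segs[0].glucose, [4.0, 6.0, 8.0, 10.0])

    def test_20min_gap_splits_into_two_segments(self):
        # 6 samples then a 20-min hole then 4 samples (derived by hand:
        # 4 missing steps > 3 allowed -> split; counts preserved 6 + 4)
        idx = np.r_[0:6, 10:14]
        s = GlucoseSeries("P1", T0 + idx * STEP5, np.linspace(5, 9, 10))
        segs = regularize(s, 5, 15)
        assert [len(g) for g in segs] == [6, 4]
        assert sum(len(g) for g in segs) == 10

    def test_already_regular_is_identity(self):
        s = regular_series([5.0, 6.0, 7.0, 8.0])
        segs = regularize(s)
        assert len(segs) == 1
        np.testing.assert_array_equal(segs[0].glucose, s.glucose)
        np.testing.assert_array_equal(segs[0].timestamps, s.timestamps)

    def test_bad_interval_param(self):
        with pytest.raises(ParameterError):
            regularize(regular_series([5.0, 6.0]), 0)

    def test_grid_alignment_and_count_preservation_random(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            idx = np.sort(rng.choice(200, size=n, replace=False))
            s = GlucoseSeries("P", T0 + idx * STEP5, rng.uniform(3, 15, n))
            try:
                segs = regularize(s, 5, 15)
            except EmptyInputError:
                continue
            total = 0
            for seg in segs:
                offs = (seg.timestamps - seg.timestamps[0]) / STEP5
                assert np.all(offs == np.round(offs))
                total += len(seg)
            # interpolation only adds samples: every original observation
            # that survived (not a dropped singleton) is in some segment
            all_seg_ts = np.concatenate([g.timestamps for g in segs])
            surviving = int(np.isin(T0 + idx * STEP5, all_seg_ts).sum())
            assert total >= surviving

    def test_empty_series_rejected(self):
        s = regular_series([5.0, 6.0])
        s.timestamps, s.glucose, s.calibration_bg = (
            s.timestamps[:0], s.glucose[:0], s.calibration_bg[:0]
        )
        with pytest.raises(EmptyInputError):
            regularize(s)


class TestSummarize:
    def test_hand_arithmetic_example(self):
        s = summarize(regular_series([2.0, 4.0, 6.0]))
        assert s.mean == 4.0
        assert s.sd == 2.0  # sample sd: sqrt(((2-4)^2+(0)+(2)^2)/2)
        assert s.min == 2.0 and s.max == 6.0

    def test_constant_series_zero_sd(self):
        assert summarize(regular_series([5.0, 5.0, 5.0])).sd == 0.0

    def test_single_sample_insufficient(self):
        with pytest.raises(InsufficientDataError):
            summarize(regular_series([5.0]))

    def test_agrees_with_streaming_moments_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(2, 200))
            vals = rng.uniform(2.5, 20.0, n)
            s = summarize(regular_series(vals))
            # Welford online moments oracle
            mean, m2 = 0.0, 0.0
            for k, x in enumerate(vals, start=1):
                d = x - mean
                mean += d / k
                m2 += d * (x - mean)
            assert abs(s.mean - mean) < 1e-9
            assert abs(s.sd - np.sqrt(m2 / (n - 1))) < 1e-9

    def test_counts_calibration_entries(self):
        cal = np.array([np.nan, 7.0, np.nan, 8.0])
        s = regular_series([5, 6, 7, 8], cal=cal)
        assert summarize(s).n_calibration == 2

    def test_pooled_summary_matches_concatenation(self):
        a = regular_series([4.0, 6.0])
        b = regular_series([8.0, 10.0])
        pooled = pooled_summary([a, b])
        assert pooled.n == 4
        assert pooled.mean == 7.0
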