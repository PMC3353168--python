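import numpy as np
import pandas as pd
import pytest

from chronowave import (
    TimeSeries,
    TimeSeriesSet,
    downsample,
    fill_missing,
    read_dataset,
    validate_for_analysis,
    write_results,
)


def _write_csv(tmp_path, text, name="data.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadDataset:
    def test_csv_columns_become_series(self, tmp_path):
        p = _write_csv(tmp_path, "a,b,c\n1,2,3\n4,5,6\n7,8,9\n1,1,1\n")
        ds = read_dataset(p)
        assert len(ds) == 3
        assert ds.dt == 1.0
        assert [s.label for s in ds] == ["a", "b", "c"]
        np.testing.assert_allclose(ds[0].values, [1, 4, 7, 1])

    def test_time_column_sets_dt(self, tmp_path):
        # 15-minute sampling expressed in hours
        rows = "\n".join(f"{0.25 * i},{i}" for i in range(8))
        p = _write_csv(tmp_path, "t,x\n" + rows + "\n")
        ds = read_dataset(p, time_column=0)
        assert ds.dt == pytest.approx(0.25)
        assert len(ds) == 1

    def test_empty_and_nan_cells_become_missing(self, tmp_path):
        p = _write_csv(tmp_path, "x\n1\n2\n\nNaN\n5\n")
        ds = read_dataset(p)
        assert list(ds[0].missing_mask) == [True, True, False, False, True]

    def test_nonuniform_time_column_rejected(self, tmp_path):
        p = _write_csv(tmp_path, "t,x\n0,1\n1,2\n2.5,3\n3.5,4\n")
        with pytest.raises(ValueError, match="uniform"):
            read_dataset(p, time_column=0)

    def test_transpose_reads_rows_as_series(self, tmp_path):
        p = _write_csv(tmp_path, "1,2,3,4\n5,6,7,8\n", name="d.csv")
        ds = read_dataset(p, has_header=False, transpose=True)
        assert len(ds) == 2
        np.testing.assert_allclose(ds[1].values, [5, 6, 7, 8])

    def test_spreadsheet_first_sheet(self, tmp_path):
        p = tmp_path / "data.xlsx"
        pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 6, 7, 8]}).to_excel(
            p, index=False
        )
        ds = read_dataset(p)
        assert [s.label for s in ds] == ["a", "b"]
        np.testing.assert_allclose(ds[1].values, [5, 6, 7, 8])

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(IOError):
            read_dataset(tmp_path / "nope.csv")


class TestBatchInvariants:
    def test_unequal_lengths_name_offenders(self):
        a = TimeSeries(np.arange(6.0), label="a")
        b = TimeSeries(np.arange(8.0), label="b")
        with pytest.raises(ValueError, match="b"):
            TimeSeriesSet([a, b])


class TestValidateForAnalysis:
    def test_defaults_pass_untouched(self):
        ds = TimeSeries(np.zeros(240), dt=1.0)
        lo, hi, msgs = validate_for_analysis(ds, 6, 48)
        assert (lo, hi) == (6, 48)
        assert msgs == []

    def test_nyquist_clamp_warns(self):
        ds = TimeSeries(np.zeros(240), dt=1.0)
        with pytest.warns(UserWarning):
            lo, hi, msgs = validate_for_analysis(ds, 0.5, 48)
        assert (lo, hi) == (2.0, 48)
        assert len(msgs) == 1 and "2" in msgs[0]

    def test_record_length_clamp(self):
        ds = TimeSeries(np.zeros(60), dt=1.0)
        with pytest.warns(UserWarning):
            lo, hi, msgs = validate_for_analysis(ds, 6, 48)
        assert (lo, hi) == (6, 30)
        assert len(msgs) == 1

    def test_idempotent(self):
        ds = TimeSeries(np.zeros(60), dt=1.0)
        with pytest.warns(UserWarning):
            lo, hi, _ = validate_for_analysis(ds, 1, 48)
        lo2, hi2, msgs2 = validate_for_analysis(ds, lo, hi)
        assert (lo2, hi2) == (lo, hi)
        assert msgs2 == []

    def test_downsample_doubles_nyquist_clamp(self):
        ts = TimeSeries(np.zeros(240), dt=1.0)
        with pytest.warns(UserWarning):
            lo1, _, _ = validate_for_analysis(ts, 1.0, 48)
        with pytest.warns(UserWarning):
            lo2, _, _ = validate_for_analysis(downsample(ts, 2), 1.0, 48)
        assert lo2 == 2 * lo1

    def test_empty_range_is_error(self):
        ds = TimeSeries(np.zeros(4), dt=10.0)
        with pytest.raises(ValueError, match="no analyzable"):
            validate_for_analysis(ds, 1, 2)


class TestFillMissing:
    def test_linear_midpoint(self):
        ts = TimeSeries([1.0, np.nan, 3.0, 4.0])
        out = fill_missing(ts, "linear")
        np.testing.assert_allclose(out.values, [1, 2, 3, 4])
        assert out.missing_mask.all()

    def test_edge_gaps_extend_nearest(self):
        ts = TimeSeries([np.nan, 2.0, 4.0, np.nan])
        out = fill_missing(ts, "linear")
        np.testing.assert_allclose(out.values, [2, 2, 4, 4])

    def test_no_missing_returns_same_object(self):
        ts = TimeSeries([1.0, 2.0, 3.0, 4.0])
        assert fill_missing(ts) is ts

    def test_all_missing_is_error(self):
        ts = TimeSeries([np.nan] * 4)
        with pytest.raises(ValueError):
            fill_missing(ts)

    @pytest.mark.parametrize("method,expected", [("zero", 0.0), ("mean", 2.5)])
    def test_other_methods(self, method, expected):
        ts = TimeSeries([1.0, np.nan, 4.0, np.nan, 1.0, 4.0])
        out = fill_missing(ts, method)
        assert out.values[1] == expected


class TestDownsample:
    def test_identity_at_factor_one(self):
        ts = TimeSeries([1.0, 3.0, 5.0, 7.0])
        assert downsample(ts, 1) is ts

    def test_block_means_and_dt(self):
        ts = TimeSeries([1.0, 3.0, 5.0, 7.0], dt=1.0)
        out = downsample(ts, 2)
        np.testing.assert_allclose(out.values, [2.0, 6.0])
        assert out.dt == 2.0

    def test_quarter_hour_to_hourly(self):
        ts = TimeSeries(np.ones(960), dt=0.25)
        out = downsample(ts, 4)
        assert out.n == 240
        assert out.dt == pytest.approx(1.0)

    def test_missing_excluded_from_blocks(self):
        ts = TimeSeries([1.0, np.nan, np.nan, np.nan, 2.0, 4.0])
        out = downsample(ts, 2)
        np.testing.assert_allclose(out.values[0], 1.0)
        assert not out.missing_mask[1]
        np.testing.assert_allclose(out.values[2], 3.0)

    def test_factor_too_large(self):
        with pytest.raises(ValueError):
            downsample(TimeSeries(np.ones(4)), 4)


class TestWriteResults:
    def test_round_trip_csv(self, tmp_path):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        (out,) = write_results({"period": table}, tmp_path / "run", format="csv")
        assert out.name == "run.period.csv"
        back = read_dataset(out)
        for j, s in enumerate(back):
            np.testing.assert_allclose(s.values, table.iloc[:, j], rtol=1e-9)

    def test_masked_entries_are_empty_cells(self, tmp_path):
        table = pd.DataFrame({"x": [1.0, np.nan, 3.0, 4.0], "y": [5.0, 6.0, 7.0, 8.0]})
        (out,) = write_results({"t": table}, tmp_path / "run")
        lines = out.read_text().strip().splitlines()
        assert lines[2] == ",6.0"  # masked entry serialized as an empty field
        back = read_dataset(out)
        assert not back[0].missing_mask[1]
        assert back[1].missing_mask.all()

    def test_two_tables_two_files(self, tmp_path):
        t = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        paths = write_results({"a": t, "b": t}, tmp_path / "out")
        assert sorted(p.name for p in paths) == ["out.a.csv", "out.b.csv"]

    def test_npz_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(16, 2)), columns=["u", "v"])
        (out,) = write_results({"m": table}, tmp_path / "run", format="npz")
        back = read_dataset(out)
        np.testing.assert_allclose(back[1].values, table["v"], rtol=1e-9)
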