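"""Tests of the series container, I/O dialects, and snapshot-matrix assembly."""

import numpy as np
import pandas as pd
import pytest

from rpodflow import (
    DataError,
    FormatError,
    InsufficientDataError,
    ValidationError,
    VelocityFieldSeries,
    build_snapshot_matrix,
    generate_synthetic_flow,
    load_series,
    save_series,
    series_from_matrix,
)


def tiny_series(m=3):
    """1x2 grid (2 valid points), m snapshots, hand-set values."""
    u = np.arange(2.0 * m).reshape(2, m)
    v = 10.0 + np.arange(2.0 * m).reshape(2, m)
    return VelocityFieldSeries(
        x=np.array([0.0, 0.01]),
        y=np.array([0.0]),
        mask=np.ones((1, 2), dtype=bool),
        u=u,
        v=v,
        times=np.arange(m, dtype=float),
        sample_rate=1.0,
    )


class TestVelocityFieldSeries:
    def test_rejects_nonmonotone_times(self):
        with pytest.raises(ValidationError):
            VelocityFieldSeries(
                x=np.array([0.0]), y=np.array([0.0]),
                mask=np.ones((1, 1), bool),
                u=np.zeros((1, 2)), v=np.zeros((1, 2)),
                times=np.array([1.0, 0.5]), sample_rate=1.0,
            )

    def test_rejects_nonfinite_at_valid_points(self):
        with pytest.raises(DataError):
            VelocityFieldSeries(
                x=np.array([0.0]), y=np.array([0.0]),
                mask=np.ones((1, 1), bool),
                u=np.array([[np.nan, 0.0]]), v=np.zeros((1, 2)),
                times=np.array([0.0, 1.0]), sample_rate=1.0,
            )

    def test_rejects_row_count_mismatch(self):
        with pytest.raises(ValidationError):
            VelocityFieldSeries(
                x=np.array([0.0, 1.0]), y=np.array([0.0]),
                mask=np.ones((1, 2), bool),
                u=np.zeros((3, 2)), v=np.zeros((3, 2)),
                times=np.array([0.0, 1.0]), sample_rate=1.0,
            )


class TestSnapshotMatrix:
    def test_block_structure_u_above_v(self):
        sm = build_snapshot_matrix(tiny_series())
        assert sm.U.shape == (4, 3)
        # rows ordered [u1, u2, v1, v2]; fluctuations of row-linear data
        expected_fluct = np.array([-1.0, 0.0, 1.0])
        for row in sm.U:
            assert np.allclose(row, expected_fluct)
        comps = [c for c, _, _ in sm.row_index()]
        assert comps == ["u", "u", "v", "v"]

    def test_rows_have_zero_mean(self, small_spec):
        series, _ = generate_synthetic_flow(small_spec)
        sm = build_snapshot_matrix(series)
        scale = np.abs(sm.U).max(axis=1) + 1e-300
        assert np.all(np.abs(sm.U.mean(axis=1)) <= 1e-9 * scale + 1e-15)

    def test_time_constant_series_gives_zero_fluctuations(self):
        s = tiny_series()
        const = VelocityFieldSeries(
            x=s.x, y=s.y, mask=s.mask,
            u=np.full((2, 3), 2.5), v=np.full((2, 3), -1.5),
            times=s.times, sample_rate=1.0,
        )
        sm = build_snapshot_matrix(const)
        assert np.all(sm.U == 0)
        assert np.allclose(sm.mean_u, 2.5) and np.allclose(sm.mean_v, -1.5)

    def test_single_snapshot_raises(self):
        with pytest.raises(InsufficientDataError):
            build_snapshot_matrix(tiny_series(m=1))

    def test_reassembly_reproduces_snapshots(self, small_spec):
        series, _ = generate_synthetic_flow(small_spec)
        sm = build_snapshot_matrix(series)
        full = sm.full_matrix()
        n = series.n_points
        assert np.allclose(full[:n], series.u, atol=1e-12)
        assert np.allclose(full[n:], series.v, atol=1e-12)

    def test_masked_points_excluded(self, small_spec):
        series, _ = generate_synthetic_flow(small_spec)
        sm = build_snapshot_matrix(series)
        assert sm.U.shape[0] == 2 * series.mask.sum()

    def test_series_from_matrix_roundtrip(self, small_spec):
        series, _ = generate_synthetic_flow(small_spec)
        sm = build_snapshot_matrix(series)
        back = series_from_matrix(sm.full_matrix(), sm)
        assert np.allclose(back.u, series.u, atol=1e-12)
        with pytest.raises(ValidationError):
            series_from_matrix(sm.U[:-1], sm)


class TestIO:
    @pytest.mark.parametrize("fmt", ["csv", "npz"])
    def test_roundtrip(self, tmp_path, small_spec, fmt):
        series, _ = generate_synthetic_flow(small_spec)
        target = save_series(series, tmp_path / "out", fmt=fmt)
        back = load_series(target)
        assert back.n_snapshots == series.n_snapshots
        assert np.array_equal(back.mask, series.mask)
        assert np.allclose(back.u, series.u, atol=1e-12)
        assert np.allclose(back.v, series.v, atol=1e-12)
        assert np.allclose(back.times, series.times, atol=1e-12)
        assert back.sample_rate == pytest.approx(series.sample_rate)

    def test_frame_count(self, tmp_path):
        save_series(tiny_series(m=3), tmp_path / "d")
        assert load_series(tmp_path / "d").n_snapshots == 3

    def test_missing_grid_row_is_format_error(self, tmp_path):
        save_series(tiny_series(m=3), tmp_path / "d")
        frame = tmp_path / "d" / "frame_0001.csv"
        df = pd.read_csv(frame)
        df.iloc[:-1].to_csv(frame, index=False)
        with pytest.raises(FormatError):
            load_series(tmp_path / "d")

    def test_inconsistent_mask_is_data_error(self, tmp_path):
        save_series(tiny_series(m=3), tmp_path / "d")
        frame = tmp_path / "d" / "frame_0002.csv"
        df = pd.read_csv(frame)
        df.loc[0, "u"] = np.nan
        df.to_csv(frame, index=False)
        with pytest.raises(DataError):
            load_series(tmp_path / "d")

    def test_empty_directory_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            load_series(tmp_path)

    def test_masked_points_written_as_nan(self, tmp_path, small_spec):
        series, _ = generate_synthetic_flow(small_spec)
        save_series(series, tmp_path / "d")
        df = pd.read_csv(tmp_path / "d" / "frame_0000.csv")
        assert df["u"].isna().sum() == (~series.mask).sum()
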