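"""Velocity-field series container, I/O, and snapshot-matrix assembly.

The central data model is :class:`VelocityFieldSeries`: a time series of 2D
velocity fields (u, v) sampled on a fixed Cartesian grid with a boolean
validity mask (vessel lumen vs. wall/outside).  Only the ``n`` valid grid
points are stored, as ``(n, m)`` arrays over the ``m`` snapshots.

:func:`build_snapshot_matrix` subtracts the per-point time-averaged velocity
and stacks the fluctuations into the ``2n x m`` snapshot matrix ``U`` used by
POD and RPCA: the u-component block occupies rows ``0..n-1`` and the
v-component block rows ``n..2n-1``, with grid points scanned row-major
(y-outer, x-inner).  That ordering is part of the on-disk and in-memory
contract; the mask and grid travel with the matrix so fields can be
re-embedded for plotting and export.

Two interchangeable on-disk dialects are supported:

* a directory of per-snapshot delimited-text tables, header ``x,y,u,v``, one
  row per grid point (NaN only at masked points), with ``times.csv`` and a
  small ``meta.yaml`` alongside;
* a single NumPy ``.npz`` container holding ``x, y, mask, u, v, times`` and
  scalar metadata.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .exceptions import DataError, FormatError, InsufficientDataError, ValidationError

__all__ = [
    "VelocityFieldSeries",
    "SnapshotMatrix",
    "load_series",
    "save_series",
    "build_snapshot_matrix",
    "series_from_matrix",
]

_FRAME_RE = re.compile(r"frame_(\d+)\.csv$")


@dataclass
class VelocityFieldSeries:
    """Gridded (u, v) snapshots over time with mask and timing metadata.

    Parameters
    ----------
    x, y
        Grid coordinates in metres, lengths ``Nx`` and ``Ny``.
    mask
        Boolean ``(Ny, Nx)`` validity grid; ``n = mask.sum()`` points are
        stored.
    u, v
        Velocity components in m/s, shape ``(n, m)``; rows follow the
        row-major (y-outer, x-inner) scan of the True mask entries.
    times
        Snapshot timestamps in seconds, strictly increasing, length ``m``.
    sample_rate
        Sampling frequency in Hz.
    cycle_period
        Optional cardiac-cycle period in seconds.
    """

    x: np.ndarray
    y: np.ndarray
    mask: np.ndarray
    u: np.ndarray
    v: np.ndarray
    times: np.ndarray
    sample_rate: float
    cycle_period: float | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.u = np.atleast_2d(np.asarray(self.u, dtype=float))
        self.v = np.atleast_2d(np.asarray(self.v, dtype=float))
        self.times = np.asarray(self.times, dtype=float)
        if self.mask.shape != (self.y.size, self.x.size):
            raise ValidationError(
                f"mask shape {self.mask.shape} does not match grid "
                f"(Ny={self.y.size}, Nx={self.x.size})"
            )
        n = int(self.mask.sum())
        if self.u.shape != self.v.shape:
            raise ValidationError("u and v shapes differ")
        if self.u.shape[0] != n:
            raise ValidationError(
                f"u has {self.u.shape[0]} rows but mask has {n} valid points"
            )
        if self.times.size != self.u.shape[1]:
            raise ValidationError("times length does not match snapshot count")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")
        if not (np.isfinite(self.u).all() and np.isfinite(self.v).all()):
            raise DataError("non-finite velocity at a valid grid point")

    @property
    def n_points(self) -> int:
        """Number of valid grid points n."""
        return self.u.shape[0]

    @property
    def n_snapshots(self) -> int:
        """Number of snapshots m."""
        return self.u.shape[1]

    def frame(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Snapshot ``j`` embedded on the full grid as ``(Ny, Nx)`` arrays.

        Masked points are NaN.
        """
        return (
            embed_field(self.u[:, j], self.mask),
            embed_field(self.v[:, j], self.mask),
        )

    def speed(self) -> np.ndarray:
        """Velocity magnitude ``sqrt(u² + v²)`` at valid points, shape (n, m)."""
        return np.hypot(self.u, self.v)


def embed_field(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Scatter a length-n vector of valid-point values onto the (Ny, Nx) grid."""
    out = np.full(mask.shape, np.nan)
    out[mask] = values
    return out


@dataclass
class SnapshotMatrix:
    """The 2n x m fluctuation matrix with its mean field and grid metadata.

    ``U[0:n]`` holds u-fluctuations and ``U[n:2n]`` v-fluctuations; each row
    has zero temporal mean.  ``mean_u``/``mean_v`` are the subtracted
    per-point time averages.
    """

    U: np.ndarray
    mean_u: np.ndarray
    mean_v: np.ndarray
    x: np.ndarray
    y: np.ndarray
    mask: np.ndarray
    times: np.ndarray
    sample_rate: float
    cycle_period: float | None = None

    @property
    def n(self) -> int:
        return self.mean_u.size

    @property
    def m(self) -> int:
        return self.U.shape[1]

    @property
    def mean_stack(self) -> np.ndarray:
        """The mean field stacked as a length-2n vector [ū; v̄]."""
        return np.concatenate([self.mean_u, self.mean_v])

    def full_matrix(self) -> np.ndarray:
        """Mean-restored 2n x m velocity matrix (fluctuations + mean)."""
        return self.U + self.mean_stack[:, None]

    def row_index(self) -> list[tuple[str, int, int]]:
        """Row -> (component, iy, ix) map for the 2n rows of ``U``."""
        iy, ix = np.nonzero(self.mask)
        return [("u", int(a), int(b)) for a, b in zip(iy, ix)] + [
            ("v", int(a), int(b)) for a, b in zip(iy, ix)
        ]

    def same_grid(self, other: "SnapshotMatrix") -> bool:
        return (
            self.mask.shape == other.mask.shape
            and np.array_equal(self.mask, other.mask)
            and np.allclose(self.x, other.x)
            and np.allclose(self.y, other.y)
        )


def build_snapshot_matrix(series: VelocityFieldSeries) -> SnapshotMatrix:
    """Assemble the mean-subtracted 2n x m snapshot matrix from a series.

    The time-averaged velocity field is computed per grid point over all m
    snapshots (all cycles pooled) and subtracted; the u-fluctuation block is
    stacked above the v-fluctuation block.

    Raises
    ------
    InsufficientDataError
        If the series has fewer than 2 snapshots.
    """
    if series.n_snapshots < 2:
        raise InsufficientDataError(
            f"need at least 2 snapshots to form fluctuations, got {series.n_snapshots}"
        )
    mean_u = series.u.mean(axis=1)
    mean_v = series.v.mean(axis=1)
    U = np.vstack([series.u - mean_u[:, None], series.v - mean_v[:, None]])
    return SnapshotMatrix(
        U=U,
        mean_u=mean_u,
        mean_v=mean_v,
        x=series.x,
        y=series.y,
        mask=series.mask,
        times=series.times,
        sample_rate=series.sample_rate,
        cycle_period=series.cycle_period,
    )


def series_from_matrix(
    full: np.ndarray, template: SnapshotMatrix
) -> VelocityFieldSeries:
    """Rebuild a :class:`VelocityFieldSeries` from a 2n x m velocity matrix.

    ``full`` must include the mean (use :meth:`SnapshotMatrix.full_matrix`
    conventions); the template supplies grid, mask and timing.
    """
    n = template.n
    if full.shape != (2 * n, template.m):
        raise ValidationError(
            f"matrix shape {full.shape} does not match template (2n={2*n}, m={template.m})"
        )
    return VelocityFieldSeries(
        x=template.x,
        y=template.y,
        mask=template.mask,
        u=full[:n],
        v=full[n:],
        times=template.times,
        sample_rate=template.sample_rate,
        cycle_period=template.cycle_period,
    )


# ---------------------------------------------------------------------------
# I/O


def save_series(series: VelocityFieldSeries, path: str | Path, fmt: str = "csv") -> Path:
    """Write a series as per-snapshot CSV frames (``fmt='csv'``) or one ``.npz``."""
    path = Path(path)
    if fmt == "npz":
        if path.suffix != ".npz":
            path = path.with_suffix(".npz")
        np.savez(
            path,
            x=series.x,
            y=series.y,
            mask=series.mask,
            u=series.u,
            v=series.v,
            times=series.times,
            sample_rate=series.sample_rate,
            cycle_period=np.nan if series.cycle_period is None else series.cycle_period,
        )
        return path
    if fmt != "csv":
        raise ValidationError(f"unknown format {fmt!r}; use 'csv' or 'npz'")
    path.mkdir(parents=True, exist_ok=True)
    X, Y = np.meshgrid(series.x, series.y)
    width = max(4, len(str(series.n_snapshots - 1)))
    for j in range(series.n_snapshots):
        u2, v2 = series.frame(j)
        df = pd.DataFrame(
            {"x": X.ravel(), "y": Y.ravel(), "u": u2.ravel(), "v": v2.ravel()}
        )
        df.to_csv(path / f"frame_{j:0{width}d}.csv", index=False)
    pd.DataFrame({"t": series.times}).to_csv(path / "times.csv", index=False)
    meta = {
        "sample_rate": float(series.sample_rate),
        "cycle_period": None if series.cycle_period is None else float(series.cycle_period),
    }
    (path / "meta.yaml").write_text(yaml.safe_dump(meta))
    return path


def _iter_frame_files(path: Path) -> Iterator[Path]:
    frames = sorted(
        (p for p in path.iterdir() if _FRAME_RE.search(p.name)),
        key=lambda p: int(_FRAME_RE.search(p.name).group(1)),
    )
    if not frames:
        raise FormatError(f"no frame_*.csv files found in {path}")
    yield from frames


def _load_frame(p: Path) -> pd.DataFrame:
    df = pd.read_csv(p)
    missing = {"x", "y", "u", "v"} - set(df.columns)
    if missing:
        raise FormatError(f"{p.name}: missing columns {sorted(missing)}")
    return df.sort_values(["y", "x"], kind="stable").reset_index(drop=True)


def load_series(path: str | Path) -> VelocityFieldSeries:
    """Load a series from a frame directory or an ``.npz`` container.

    The grid and mask are inferred from the first frame (masked points are
    those with NaN velocity); every subsequent frame is validated against
    them.

    Raises
    ------
    FormatError
        Inconsistent grids or masks across frames, or malformed files.
    DataError
        Non-finite velocity at a valid grid point.
    """
    path = Path(path)
    if path.is_file() and path.suffix == ".npz":
        with np.load(path) as z:
            cp = float(z["cycle_period"])
            return VelocityFieldSeries(
                x=z["x"],
                y=z["y"],
                mask=z["mask"],
                u=z["u"],
                v=z["v"],
                times=z["times"],
                sample_rate=float(z["sample_rate"]),
                cycle_period=None if np.isnan(cp) else cp,
            )
    if not path.is_dir():
        raise FormatError(f"{path} is neither a directory nor an .npz container")

    frames = list(_iter_frame_files(path))
    first = _load_frame(frames[0])
    x = np.unique(first["x"].to_numpy())
    y = np.unique(first["y"].to_numpy())
    if first.shape[0] != x.size * y.size:
        raise FormatError(
            f"{frames[0].name}: {first.shape[0]} rows, expected full "
            f"{y.size} x {x.size} grid"
        )
    ref_xy = first[["x", "y"]].to_numpy()
    valid2d = np.isfinite(first["u"].to_numpy()) & np.isfinite(first["v"].to_numpy())
    mask = valid2d.reshape(y.size, x.size)

    u_cols, v_cols = [], []
    for p, df in zip(frames, map(_load_frame, frames)):
        if df.shape[0] != ref_xy.shape[0] or not np.allclose(
            df[["x", "y"]].to_numpy(), ref_xy
        ):
            raise FormatError(f"{p.name}: grid differs from first frame")
        uj = df["u"].to_numpy()
        vj = df["v"].to_numpy()
        valid_j = np.isfinite(uj) & np.isfinite(vj)
        if not np.array_equal(valid_j, valid2d):
            raise DataError(f"{p.name}: NaN pattern differs from first frame mask")
        u_cols.append(uj[valid2d])
        v_cols.append(vj[valid2d])

    times_file = path / "times.csv"
    m = len(frames)
    if times_file.exists():
        times = pd.read_csv(times_file)["t"].to_numpy(dtype=float)
        if times.size != m:
            raise FormatError("times.csv length does not match frame count")
    else:
        times = np.arange(m, dtype=float)
    meta_file = path / "meta.yaml"
    sample_rate = 1.0
    cycle_period = None
    if meta_file.exists():
        meta = yaml.safe_load(meta_file.read_text()) or {}
        sample_rate = float(meta.get("sample_rate", 1.0))
        cp = meta.get("cycle_period")
        cycle_period = None if cp is None else float(cp)
    elif times.size >= 2:
        sample_rate = 1.0 / float(np.mean(np.diff(times)))

    return VelocityFieldSeries(
        x=x,
        y=y,
        mask=mask,
        u=np.column_stack(u_cols),
        v=np.column_stack(v_cols),
        times=times,
        sample_rate=sample_rate,
        cycle_period=cycle_period,
    )
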