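"""Reading, validation, resampling and writing of uniformly sampled time series.

A dataset is a batch of equal-length traces sharing one sampling interval
(hours by default).  Missing observations are first-class: they are carried
in a boolean mask and treated as absent (never as zero) by every analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "TimeSeriesSet",
    "read_dataset",
    "validate_for_analysis",
    "fill_missing",
    "downsample",
    "write_results",
]


@dataclass
class TimeSeries:
    """One uniformly sampled trace.

    Parameters
    ----------
    values : array of float
        Sample values in arbitrary signal units.  Non-finite entries are
        recorded as missing.
    dt : float
        Sampling interval in time units (default 1 hour).
    t0 : float
        Time of the first sample, same units as ``dt``.
    missing_mask : array of bool, optional
        ``True`` where a sample was observed.  Defaults to the finiteness
        of ``values``.
    label : str
        Identifier used in output tables.
    """

    values: np.ndarray
    dt: float = 1.0
    t0: float = 0.0
    missing_mask: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.values.size < 2:
            raise ValueError("a time series needs at least 2 samples")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.missing_mask is None:
            self.missing_mask = np.isfinite(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask must match values in length")
            self.missing_mask = self.missing_mask & np.isfinite(self.values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def time(self) -> np.ndarray:
        """Sample times ``t0 + i*dt``."""
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def has_missing(self) -> bool:
        return not bool(self.missing_mask.all())

    def observed_values(self) -> np.ndarray:
        return self.values[self.missing_mask]


@dataclass
class TimeSeriesSet:
    """An ordered batch of equal-length traces sharing one ``dt``."""

    series: list[TimeSeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError("a TimeSeriesSet needs at least one series")
        n0, dt0 = self.series[0].n, self.series[0].dt
        bad = [s.label or str(i) for i, s in enumerate(self.series) if s.n != n0]
        if bad:
            raise ValueError(
                "all series in a batch must contain an equal number of "
                f"observations; offending columns: {', '.join(bad)}"
            )
        if any(not np.isclose(s.dt, dt0, rtol=1e-9) for s in self.series):
            raise ValueError("all series in a batch must share the same dt")

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self) -> Iterator[TimeSeries]:
        return iter(self.series)

    def __getitem__(self, i: int) -> TimeSeries:
        return self.series[i]

    @property
    def dt(self) -> float:
        return self.series[0].dt

    @property
    def n(self) -> int:
        return self.series[0].n


_TEXT_FORMATS = {".csv": "csv", ".tsv": "tsv", ".txt": "txt"}


def _sniff_format(path: Path, format_hint: str | None) -> str:
    if format_hint is not None:
        return format_hint
    suffix = path.suffix.lower()
    if suffix in _TEXT_FORMATS:
        return _TEXT_FORMATS[suffix]
    if suffix in {".xlsx", ".xlsm"}:
        return "spreadsheet"
    if suffix == ".npz":
        return "npz"
    raise ValueError(f"cannot infer format of {path}; pass format_hint")


def _frame_to_set(
    frame: pd.DataFrame, time_column: int | None, transpose: bool
) -> TimeSeriesSet:
    if transpose:
        frame = frame.T.reset_index(drop=True)
        frame.columns = [str(c) for c in frame.columns]
    dt, t0 = 1.0, 0.0
    if time_column is not None:
        t = pd.to_numeric(frame.iloc[:, time_column], errors="coerce").to_numpy(float)
        if np.any(~np.isfinite(t)):
            raise ValueError("time column contains non-numeric entries")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ValueError("time column must be strictly increasing")
        dt = float(np.mean(steps))
        dev = float(np.max(np.abs(steps - dt)))
        if dev > 1e-6 * max(abs(dt), 1.0):
            raise ValueError(
                f"time column is not uniformly spaced (max deviation {dev:g})"
            )
        t0 = float(t[0])
        frame = frame.drop(columns=frame.columns[time_column])
    series = []
    for name in frame.columns:
        col = pd.to_numeric(frame[name], errors="coerce").to_numpy(float)
        series.append(TimeSeries(values=col, dt=dt, t0=t0, label=str(name)))
    return TimeSeriesSet(series)


def read_dataset(
    path: str | Path,
    format_hint: str | None = None,
    has_header: bool = True,
    time_column: int | None = None,
    transpose: bool = False,
) -> TimeSeriesSet:
    """Read a batch of traces from delimited text, a spreadsheet, or ``.npz``.

    Columns are series and rows are time points (use ``transpose`` for the
    opposite layout).  Empty cells and non-numeric tokens (including the
    token ``NaN`` in any case) become missing values.  When ``time_column``
    is given, ``dt`` and ``t0`` are inferred from it; the column must be
    strictly increasing and uniformly spaced to a relative 1e-6.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = _sniff_format(path, format_hint)
    header = 0 if has_header else None
    if fmt == "csv":
        frame = pd.read_csv(path, header=header, skipinitialspace=True, skip_blank_lines=False)
    elif fmt == "tsv":
        frame = pd.read_csv(path, sep="\t", header=header, skip_blank_lines=False)
    elif fmt == "txt":
        frame = pd.read_csv(path, sep=r"\s+", header=header)
    elif fmt == "spreadsheet":
        frame = pd.read_excel(path, sheet_name=0, header=header)
    elif fmt == "npz":
        with np.load(path, allow_pickle=False) as npz:
            data = np.asarray(npz["data"], dtype=float)
            labels = (
                [str(x) for x in npz["labels"]]
                if "labels" in npz.files
                else [f"series_{i}" for i in range(data.shape[1])]
            )
            dt = float(npz["dt"]) if "dt" in npz.files else 1.0
            t0 = float(npz["t0"]) if "t0" in npz.files else 0.0
        if transpose:
            data = data.T
        return TimeSeriesSet(
            [
                TimeSeries(values=data[:, j], dt=dt, t0=t0, label=labels[j])
                for j in range(data.shape[1])
            ]
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not has_header:
        frame.columns = [f"series_{i}" for i in range(frame.shape[1])]
    return _frame_to_set(frame, time_column, transpose)


def validate_for_analysis(
    dataset: TimeSeriesSet | TimeSeries, min_period: float, max_period: float
) -> tuple[float, float, list[str]]:
    """Clamp requested period bounds to what the record can support.

    The shortest analyzable period is the Nyquist limit ``2*dt``; the
    longest is half the record, ``n*dt/2``.  A warning string is returned
    (and emitted via :mod:`warnings`) for each bound that was changed,
    reporting the bound actually used.
    """
    if min_period > max_period:
        raise ValueError("min_period must not exceed max_period")
    dt = dataset.dt
    n = dataset.n
    if n < 4:
        raise ValueError("analysis needs at least 4 samples")
    clamped_min = max(float(min_period), 2.0 * dt)
    clamped_max = min(float(max_period), n * dt / 2.0)
    msgs: list[str] = []
    if clamped_min != float(min_period):
        msgs.append(
            f"minimum period raised from {min_period:g} to the Nyquist "
            f"limit {clamped_min:g}"
        )
    if clamped_max != float(max_period):
        msgs.append(
            f"maximum period lowered from {max_period:g} to half the "
            f"record length, {clamped_max:g}"
        )
    if clamped_min > clamped_max:
        raise ValueError(
            f"no analyzable periods: record supports "
            f"[{2 * dt:g}, {n * dt / 2:g}]"
        )
    for m in msgs:
        warnings.warn(m, stacklevel=2)
    return clamped_min, clamped_max, msgs


def fill_missing(series: TimeSeries, method: str = "linear") -> TimeSeries:
    """Impute missing samples so the transforms can run on a gapless trace.

    ``linear`` interpolates between flanking observations (leading/trailing
    gaps take the nearest observed value), ``mean`` substitutes the observed
    mean, ``zero`` substitutes zero.  Callers keep the original mask to
    flag imputed stretches in downstream outputs.
    """
    mask = series.missing_mask
    n_obs = int(mask.sum())
    if n_obs == 0:
        raise ValueError("cannot fill an all-missing series")
    if n_obs < 2:
        raise ValueError("fill_missing needs at least 2 observed samples")
    if not series.has_missing:
        return series
    values = series.values.copy()
    idx = np.arange(series.n)
    if method == "linear":
        # np.interp holds the first/last observed value across edge gaps
        values[~mask] = np.interp(idx[~mask], idx[mask], values[mask])
    elif method == "mean":
        values[~mask] = values[mask].mean()
    elif method == "zero":
        values[~mask] = 0.0
    else:
        raise ValueError(f"unknown fill method {method!r}")
    return replace(series, values=values, missing_mask=np.ones(series.n, bool))


def downsample(series: TimeSeries, factor: int) -> TimeSeries:
    """Block-average ``factor`` consecutive samples into one.

    Missing samples are excluded from each block mean; a block with no
    observed samples stays missing.  ``dt`` is multiplied by ``factor``.
    A partial final block is averaged over the samples it has.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    if factor == 1:
        return series
    if factor >= series.n:
        raise ValueError(f"factor {factor} must be smaller than n={series.n}")
    n_blocks = int(np.ceil(series.n / factor))
    values = np.full(n_blocks, np.nan)
    mask = np.zeros(n_blocks, bool)
    for b in range(n_blocks):
        sl = slice(b * factor, (b + 1) * factor)
        m = series.missing_mask[sl]
        if m.any():
            values[b] = series.values[sl][m].mean()
            mask[b] = True
    return replace(
        series,
        values=values,
        missing_mask=mask,
        dt=series.dt * factor,
        t0=series.t0 + series.dt * (factor - 1) / 2.0,
    )


def write_results(
    tables: dict[str, pd.DataFrame],
    path: str | Path,
    format: str = "csv",
) -> list[Path]:
    """Write named tables as ``<stem>.<table>.<ext>`` files.

    Missing values are serialized as empty fields in text formats.  With
    ``format="npz"`` each table is stored as one compressed array archive.
    Returns the paths written.
    """
    if not tables:
        raise ValueError("no tables to write")
    path = Path(path)
    stem = path.parent / (path.stem if path.suffix else path.name)
    written: list[Path] = []
    for name, table in tables.items():
        if format in ("csv", "tsv"):
            out = Path(f"{stem}.{name}.{format}")
            sep = "," if format == "csv" else "\t"
            table.to_csv(out, sep=sep, index=False)
        elif format == "npz":
            out = Path(f"{stem}.{name}.npz")
            np.savez_compressed(
                out,
                data=table.to_numpy(dtype=float),
                labels=np.array([str(c) for c in table.columns]),
            )
        else:
            raise ValueError(f"unknown output format {format!r}")
        written.append(out)
    return written
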