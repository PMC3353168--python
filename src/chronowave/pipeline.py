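"""Batch orchestration: configuration, CWT/DWT pipelines, and plot export."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cwt import MorletParams, CwtResult, morlet_cwt
from .features import FeatureTrack, extract_features, rayleigh_sync
from .modwt import (
    DEFAULT_FILTER,
    ModwtResult,
    band_label,
    denoise_by_pvalue,
    detrend_by_band,
    modwt,
    test_levels,
)
from .ridge import ClimberParams, Ridge, ridge_crazy_climber, ridge_local_max
from .signal_io import (
    TimeSeries,
    TimeSeriesSet,
    fill_missing,
    validate_for_analysis,
    write_results,
)

__all__ = ["AnalysisConfig", "run_cwt_batch", "run_dwt_batch", "render_plots"]

log = logging.getLogger("chronowave")


@dataclass(frozen=True)
class AnalysisConfig:
    """Resolved analysis settings; defaults target hourly circadian records."""

    min_period: float = 6.0
    max_period: float = 48.0
    dt: float = 1.0
    edge_mode: str = "truncate"
    ridge_method: str = "local_max"
    alpha: float = 0.05
    voices_per_octave: int = 16
    omega0: float = 6.0
    filter_name: str = DEFAULT_FILTER
    fill_method: str = "linear"
    seed: int = 0
    out_stem: str = "chronowave_out"
    out_format: str = "csv"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        return cls(**json.loads(text))

    def morlet_params(self, clamped_min: float, clamped_max: float) -> MorletParams:
        return MorletParams(
            omega0=self.omega0,
            voices_per_octave=self.voices_per_octave,
            min_period=clamped_min,
            max_period=clamped_max,
            edge_mode=self.edge_mode,
        )


@dataclass
class CwtBatchResult:
    """Per-series transforms, ridges and feature tracks plus run metadata."""

    results: list[CwtResult]
    ridges: list[Ridge]
    tracks: list[FeatureTrack]
    skipped: list[str]
    warnings: list[str]
    config: AnalysisConfig


def _extract_ridge(result: CwtResult, config: AnalysisConfig) -> Ridge:
    if config.ridge_method == "local_max":
        return ridge_local_max(result)
    if config.ridge_method == "crazy_climber":
        return ridge_crazy_climber(result, ClimberParams(seed=config.seed))
    raise ValueError(f"unknown ridge method {config.ridge_method!r}")


def run_cwt_batch(dataset: TimeSeriesSet, config: AnalysisConfig) -> CwtBatchResult:
    """fill_missing -> Morlet CWT -> edge correction -> ridge -> features.

    Per-series failures are logged and skipped; the batch fails only when
    every series fails.  The feature tables mask estimates at imputed
    samples only in the event lists, not the period track (the wavelet
    interpolates across interior gaps).
    """
    cmin, cmax, warns = validate_for_analysis(dataset, config.min_period, config.max_period)
    params = config.morlet_params(cmin, cmax)
    out = CwtBatchResult([], [], [], [], warns, config)
    for series in dataset:
        t_start = time.perf_counter()
        try:
            filled = fill_missing(series, config.fill_method)
            result = morlet_cwt(filled, params)
            ridge = _extract_ridge(result, config)
            track = extract_features(result, ridge)
        except Exception as exc:  # noqa: BLE001 - batch error policy
            log.warning("skipping series %r: %s", series.label, exc)
            out.skipped.append(series.label)
            continue
        log.info(
            "series %r analyzed in %.3f s", series.label,
            time.perf_counter() - t_start,
        )
        out.results.append(result)
        out.ridges.append(ridge)
        out.tracks.append(track)
    if not out.tracks:
        raise RuntimeError("all series failed CWT analysis")
    return out


def cwt_tables(batch: CwtBatchResult) -> dict[str, pd.DataFrame]:
    """Assemble batch outputs as named tables (period/phase/amplitude/events)."""
    time_axis = batch.tracks[0].time
    tables: dict[str, pd.DataFrame] = {}
    for name in ("period", "phase", "amplitude"):
        cols = {"time": time_axis}
        for track in batch.tracks:
            vals = getattr(track, name)
            cols[track.label or "series"] = np.where(track.valid, vals, np.nan)
        tables[name] = pd.DataFrame(cols)
    events = []
    for track in batch.tracks:
        for kind, arr in (("peak", track.peaks), ("trough", track.troughs)):
            for t in arr:
                events.append({"series": track.label, "type": kind, "time": t})
    tables["events"] = pd.DataFrame(events, columns=["series", "type", "time"])
    if len(batch.tracks) >= 2:
        ray = rayleigh_sync(batch.tracks)
        tables["rayleigh"] = pd.DataFrame(
            {"time": time_axis, "R": ray.R, "p_value": ray.p_value, "n": ray.n}
        )
    return tables


def run_dwt_batch(
    dataset: TimeSeriesSet, config: AnalysisConfig, mode: str = "decompose"
) -> dict[str, pd.DataFrame]:
    """Band decomposition, p-value denoising, or period-band detrending.

    ``decompose`` emits one band table per series plus the level-test
    table; ``denoise``/``detrend`` emit one table of processed traces.
    """
    if mode not in ("decompose", "denoise", "detrend"):
        raise ValueError(f"unknown dwt mode {mode!r}")
    tables: dict[str, pd.DataFrame] = {}
    processed: dict[str, np.ndarray] = {}
    level_rows = []
    skipped = []
    for series in dataset:
        try:
            filled = fill_missing(series, config.fill_method)
            if mode == "decompose":
                res = modwt(filled, filter_name=config.filter_name)
                cols = {"time": filled.time}
                for j in range(1, res.J + 1):
                    cols[band_label(j, res.dt)] = res.details[j - 1]
                cols["smooth"] = res.smooth
                tables[f"bands_{series.label or 'series'}"] = pd.DataFrame(cols)
                for t in test_levels(res, alpha=config.alpha):
                    level_rows.append(
                        {
                            "series": series.label,
                            "level": t.level,
                            "band_low": 2.0**t.level * res.dt,
                            "band_high": 2.0 ** (t.level + 1) * res.dt,
                            "statistic": t.statistic,
                            "dof": t.dof,
                            "p_value": t.p_value,
                        }
                    )
            elif mode == "denoise":
                processed[series.label] = denoise_by_pvalue(
                    filled, alpha=config.alpha, filter_name=config.filter_name
                ).values
            else:
                processed[series.label] = detrend_by_band(
                    filled,
                    config.min_period,
                    config.max_period,
                    filter_name=config.filter_name,
                ).values
        except Exception as exc:  # noqa: BLE001 - batch error policy
            log.warning("skipping series %r: %s", series.label, exc)
            skipped.append(series.label)
    if mode == "decompose":
        if not tables:
            raise RuntimeError("all series failed DWT analysis")
        tables["level_tests"] = pd.DataFrame(level_rows)
    else:
        if not processed:
            raise RuntimeError("all series failed DWT analysis")
        frame = pd.DataFrame({"time": dataset[0].time} | processed)
        tables[mode] = frame
    return tables


PLOT_KINDS = ("heatmap", "period", "features", "decomposition", "overlay")


def render_plots(
    batch: CwtBatchResult | None,
    out_stem: str | Path,
    kinds: tuple[str, ...] = ("heatmap",),
    dwt_result: ModwtResult | None = None,
    series: TimeSeries | None = None,
    fmt: str = "png",
) -> list[Path]:
    """Static plot export: scalogram, period track, features, band panels.

    The heatmap shows CWT modulus over time with period on a log axis,
    ridge overlay, and black masking of edge-invalid cells; the
    decomposition stacks one panel per band; the overlay marks inferred
    peaks/troughs on the raw trace.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written: list[Path] = []
    stem = Path(out_stem)
    for kind in kinds:
        if kind not in PLOT_KINDS:
            raise ValueError(f"unknown plot kind {kind!r}; choose from {PLOT_KINDS}")
        out = stem.parent / f"{stem.name}.{kind}.{fmt}"
        if kind in ("heatmap", "period", "features", "overlay"):
            if batch is None or not batch.results:
                raise ValueError(f"plot kind {kind!r} needs CWT results")
            result, ridge, track = batch.results[0], batch.ridges[0], batch.tracks[0]
            if kind == "heatmap":
                fig, ax = plt.subplots(figsize=(9, 4))
                mod = result.modulus.copy()
                masked = np.ma.array(mod, mask=~result.edge_valid
                                     if result.params.edge_mode == "truncate" else None)
                cmap = plt.get_cmap("viridis").copy()
                cmap.set_bad("black")
                ax.pcolormesh(result.time, result.periods, masked, cmap=cmap, shading="auto")
                ax.plot(result.time[ridge.valid], ridge.period[ridge.valid], "g-", lw=1.5)
                ax.set_yscale("log")
                ax.set_xlabel("time (h)")
                ax.set_ylabel("period (h)")
            elif kind == "period":
                fig, ax = plt.subplots(figsize=(9, 3))
                ax.plot(track.time, np.where(track.valid, track.period, np.nan))
                ax.set_xlabel("time (h)")
                ax.set_ylabel("period (h)")
            elif kind == "features":
                fig, axes = plt.subplots(2, 1, figsize=(9, 5), sharex=True)
                axes[0].plot(track.time, np.where(track.valid, track.amplitude, np.nan))
                axes[0].set_ylabel("amplitude")
                axes[1].plot(track.time, np.where(track.valid, track.phase, np.nan))
                axes[1].set_ylabel("phase (rad)")
                axes[1].set_xlabel("time (h)")
            else:  # overlay
                fig, ax = plt.subplots(figsize=(9, 3))
                src = series if series is not None else None
                if src is None:
                    raise ValueError("overlay plot needs the raw series")
                ax.plot(src.time, src.values, "b-", lw=0.8)
                for pk in track.peaks:
                    ax.axvline(pk, color="g", lw=0.8)
                for tr in track.troughs:
                    ax.axvline(tr, color="g", lw=0.8, ls="--")
                ax.set_xlabel("time (h)")
                ax.set_ylabel("signal")
        else:  # decomposition
            if dwt_result is None:
                raise ValueError("decomposition plot needs a ModwtResult")
            J = dwt_result.J
            fig, axes = plt.subplots(J + 1, 1, figsize=(9, 1.2 * (J + 1)), sharex=True)
            taxis = dwt_result.dt * np.arange(dwt_result.n)
            for j in range(J):
                axes[j].plot(taxis, dwt_result.details[j], lw=0.7)
                axes[j].set_ylabel(band_label(j + 1, dwt_result.dt), fontsize=7)
            axes[J].plot(taxis, dwt_result.smooth, lw=0.7)
            axes[J].set_ylabel("smooth", fontsize=7)
            axes[J].set_xlabel("time (h)")
        fig.tight_layout()
        fig.savefig(out, dpi=120)
        plt.close(fig)
        written.append(out)
    return written


def save_tables(
    tables: dict[str, pd.DataFrame], config: AnalysisConfig
) -> list[Path]:
    paths = write_results(tables, config.out_stem, format=config.out_format)
    run_log = Path(f"{config.out_stem}.runlog.txt")
    run_log.write_text(config.to_json() + "\n")
    return paths + [run_log]
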