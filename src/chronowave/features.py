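"""Instantaneous rhythm features from a CWT ridge.

The analytic Morlet coefficient along the ridge carries the oscillation's
instantaneous phase (its argument) and amplitude (its modulus, calibrated
to signal units).  Peaks fall where the unwrapped ridge phase crosses even
multiples of pi, troughs at odd multiples — the convention under which a
cosine's coefficient is real and positive at its maxima.  Phase vectors
across a batch of oscillators feed the Rayleigh synchronization statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cwt import CwtResult
from .ridge import Ridge
from .signal_io import TimeSeries

__all__ = [
    "FeatureTrack",
    "RayleighResult",
    "extract_features",
    "rayleigh_sync",
    "peak_to_trough",
]


@dataclass
class FeatureTrack:
    """Per-time-point period/phase/amplitude plus peak and trough times.

    ``valid`` marks time points with a reportable estimate: the ridge was
    found and, under truncate edge correction, the ridge cell lies outside
    the cone of influence.  Event times are in data time units at
    sub-sample resolution.
    """

    time: np.ndarray
    period: np.ndarray
    phase: np.ndarray
    amplitude: np.ndarray
    valid: np.ndarray
    peaks: np.ndarray = field(default_factory=lambda: np.empty(0))
    troughs: np.ndarray = field(default_factory=lambda: np.empty(0))
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        """Tabular view; invalid entries are reported as missing."""
        out = pd.DataFrame(
            {
                "time": self.time,
                "period": np.where(self.valid, self.period, np.nan),
                "phase": np.where(self.valid, self.phase, np.nan),
                "amplitude": np.where(self.valid, self.amplitude, np.nan),
                "valid": self.valid.astype(int),
            }
        )
        return out


@dataclass
class RayleighResult:
    """Mean resultant length R and Rayleigh p-value per time point."""

    R: np.ndarray
    p_value: np.ndarray
    n: np.ndarray


def _phase_crossings(
    t: np.ndarray, unwrapped: np.ndarray, levels: np.ndarray
) -> list[float]:
    """Sub-sample times where the unwrapped phase first crosses each level."""
    out: list[float] = []
    for lev in levels:
        above = unwrapped >= lev
        if above[0]:
            # level already passed at segment start; count it only if the
            # first sample sits essentially on the level
            if abs(unwrapped[0] - lev) < 1e-9:
                out.append(float(t[0]))
            continue
        idx = np.flatnonzero(~above[:-1] & above[1:])
        if idx.size == 0:
            continue
        i = int(idx[0])
        frac = (lev - unwrapped[i]) / (unwrapped[i + 1] - unwrapped[i])
        out.append(float(t[i] + frac * (t[i + 1] - t[i])))
    return out


def _dedupe(times: list[float], min_sep: float) -> np.ndarray:
    kept: list[float] = []
    for x in sorted(times):
        if not kept or x - kept[-1] >= min_sep:
            kept.append(x)
    return np.asarray(kept)


def extract_features(result: CwtResult, ridge: Ridge) -> FeatureTrack:
    """Instantaneous period/phase/amplitude along a ridge, with events.

    Phase is the argument of the ridge coefficient, wrapped to (-pi, pi];
    amplitude is the (cosine-calibrated) ridge modulus in signal units.
    Peak and trough times are located by linear interpolation of the
    unwrapped phase within each contiguous valid run; events inside
    edge-invalid regions are suppressed, and peaks closer together than
    half the shortest analyzed period are merged.
    """
    cols = np.arange(result.n)
    coeff = result.coefficients[ridge.row_index, cols]
    phase = np.angle(coeff)
    # wrap to (-pi, pi]: numpy returns [-pi, pi)
    phase = np.where(phase <= -np.pi, np.pi, phase)
    amplitude = np.abs(coeff)
    valid = ridge.valid.copy()
    if result.params.edge_mode == "truncate":
        valid &= result.edge_valid[ridge.row_index, cols]
    time = result.time
    min_sep = 0.5 * float(result.periods[0])
    peaks: list[float] = []
    troughs: list[float] = []
    if valid.any():
        padded = np.r_[False, valid, False]
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        stops = np.flatnonzero(~padded[1:] & padded[:-1]) - 1
        for a, b in zip(starts, stops):
            if b - a < 1:
                continue
            seg_t = time[a : b + 1]
            seg_phi = np.unwrap(phase[a : b + 1])
            two_pi = 2.0 * np.pi
            lo, hi = seg_phi.min(), seg_phi.max()
            peak_levels = two_pi * np.arange(np.ceil(lo / two_pi), np.floor(hi / two_pi) + 1)
            trough_levels = two_pi * np.arange(
                np.ceil((lo - np.pi) / two_pi), np.floor((hi - np.pi) / two_pi) + 1
            ) + np.pi
            peaks += _phase_crossings(seg_t, seg_phi, peak_levels)
            troughs += _phase_crossings(seg_t, seg_phi, trough_levels)
    return FeatureTrack(
        time=time,
        period=ridge.period,
        phase=phase,
        amplitude=amplitude,
        valid=valid,
        peaks=_dedupe(peaks, min_sep),
        troughs=_dedupe(troughs, min_sep),
        label=result.label,
    )


def rayleigh_sync(tracks: list[FeatureTrack]) -> RayleighResult:
    """Rayleigh synchronization across a batch of phase tracks.

    At each time point with n >= 2 valid phases, R is the mean resultant
    length of the unit phase vectors and the p-value uses the standard
    second-order small-sample approximation
    ``exp(-Z) * (1 + (2Z - Z^2) / (4n))`` with ``Z = n R^2``, clamped to
    (0, 1].  Time points with fewer than 2 valid phases are missing.
    """
    if len(tracks) < 2:
        raise ValueError("rayleigh_sync needs at least 2 tracks")
    lengths = {t.phase.size for t in tracks}
    if len(lengths) != 1:
        raise ValueError("all tracks must have equal length")
    phases = np.vstack([t.phase for t in tracks])
    valid = np.vstack([t.valid for t in tracks])
    n = valid.sum(axis=0)
    z = np.exp(1j * phases)
    z[~valid] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.abs(z.sum(axis=0)) / np.maximum(n, 1)
        Z = n * R**2
        p = np.exp(-Z) * (1.0 + (2.0 * Z - Z**2) / (4.0 * np.maximum(n, 1)))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    R = np.where(n >= 2, R, np.nan)
    p = np.where(n >= 2, p, np.nan)
    return RayleighResult(R=R, p_value=p, n=n)


def peak_to_trough(track: FeatureTrack, series: TimeSeries) -> pd.DataFrame:
    """Pair each peak with the following trough and measure the excursion.

    Raw values are the original series at the sample nearest each event;
    ``excursion = raw_peak_value - raw_trough_value``.  Events that cannot
    be paired are omitted; an empty table is not an error.
    """
    rows = []
    troughs = np.asarray(track.troughs)
    for pk in np.asarray(track.peaks):
        later = troughs[troughs > pk]
        if later.size == 0:
            continue
        tr = float(later[0])
        i_pk = int(np.clip(round((pk - series.t0) / series.dt), 0, series.n - 1))
        i_tr = int(np.clip(round((tr - series.t0) / series.dt), 0, series.n - 1))
        rows.append(
            {
                "peak_time": pk,
                "trough_time": tr,
                "raw_peak_value": series.values[i_pk],
                "raw_trough_value": series.values[i_tr],
                "excursion": series.values[i_pk] - series.values[i_tr],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "peak_time",
            "trough_time",
            "raw_peak_value",
            "raw_trough_value",
            "excursion",
        ],
    )
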