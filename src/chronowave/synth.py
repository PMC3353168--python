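"""Synthetic oscillatory fixtures.

These generators emulate the standard bench signals for circadian wavelet
analysis: a frequency chirp with decaying amplitude (period sliding from
24 h to 18 h over ten days), a stable oscillation with a censored middle
segment, a non-sinusoidal wheel-running-like count record sampled every 15
minutes, and plain Gaussian white noise for significance-test calibration.
Every generator is a pure function of its spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import TimeSeries

__all__ = [
    "ChirpSpec",
    "ActivitySpec",
    "make_signal_a",
    "make_signal_b",
    "make_activity",
    "make_white_noise",
]


@dataclass(frozen=True)
class ChirpSpec:
    """Chirp with linearly sliding period and exponentially decaying amplitude.

    Defaults: ten days sampled hourly, period sliding 24 -> 18 h, amplitude
    decaying at 0.005 per hour (to ~30% of its initial value by the end of
    the record), zero baseline, no noise.
    """

    period_start: float = 24.0
    period_end: float = 18.0
    duration: float = 240.0
    dt: float = 1.0
    amplitude0: float = 1.0
    amp_decay_rate: float = 0.005
    baseline: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.period_start, self.period_end) <= 2.0 * self.dt:
            raise ValueError("periods must exceed the Nyquist limit 2*dt")
        if self.duration < 2.0 * max(self.period_start, self.period_end):
            raise ValueError("duration must cover at least two cycles")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class ActivitySpec:
    """Square-bout activity record: counts during the active half of each cycle.

    Defaults reproduce a ten-day wheel-running record sampled every 15
    minutes (960 samples) with a 24 h cycle: Poisson counts of mean
    ``bout_mean`` during the active fraction of each cycle, near-zero
    counts otherwise, plus a Poisson noise floor.
    """

    period: float = 24.0
    dt: float = 0.25
    duration: float = 240.0
    active_fraction: float = 0.5
    bout_mean: float = 50.0
    noise: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be an integral number of samples")
        if not (0.0 < self.active_fraction < 1.0):
            raise ValueError("active_fraction must lie in (0, 1)")
        if self.noise < 0 or self.bout_mean < 0:
            raise ValueError("count parameters must be nonnegative")


def chirp_phase(spec: ChirpSpec, t: np.ndarray) -> np.ndarray:
    """Closed-form phase 2*pi*Integral(du/P(u)) for the linear period ramp."""
    t = np.asarray(t, dtype=float)
    rate = (spec.period_end - spec.period_start) / spec.duration
    if abs(rate) < 1e-15:
        return 2.0 * np.pi * t / spec.period_start
    return 2.0 * np.pi * np.log1p(rate * t / spec.period_start) / rate


def chirp_period(spec: ChirpSpec, t: np.ndarray) -> np.ndarray:
    """Instantaneous period P(t), interpolating linearly over the record."""
    t = np.asarray(t, dtype=float)
    return spec.period_start + (spec.period_end - spec.period_start) * t / spec.duration


def make_signal_a(spec: ChirpSpec | None = None) -> TimeSeries:
    """Chirp test signal: sliding period, stable baseline, decaying amplitude."""
    if spec is None:
        spec = ChirpSpec()
    n = int(round(spec.duration / spec.dt))
    t = spec.dt * np.arange(n)
    x = spec.baseline + spec.amplitude0 * np.exp(
        -spec.amp_decay_rate * t
    ) * np.cos(chirp_phase(spec, t))
    if spec.noise_sd > 0:
        x = x + np.random.default_rng(spec.seed).normal(0.0, spec.noise_sd, n)
    return TimeSeries(values=x, dt=spec.dt, label="signal_a")


def make_signal_b(
    period: float = 24.0,
    duration: float = 240.0,
    dt: float = 1.0,
    gap_start_frac: float = 0.4,
    gap_end_frac: float = 0.6,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TimeSeries:
    """Fixed-period cosine with a censored middle segment.

    Samples whose time falls in ``[gap_start_frac, gap_end_frac) * duration``
    are marked missing; observed values are exactly the uncensored cosine.
    """
    if not (0.0 <= gap_start_frac <= gap_end_frac <= 1.0):
        raise ValueError("gap fractions must satisfy 0 <= start <= end <= 1")
    n = int(round(duration / dt))
    t = dt * np.arange(n)
    x = np.cos(2.0 * np.pi * t / period)
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    mask = ~((t >= gap_start_frac * duration) & (t < gap_end_frac * duration))
    return TimeSeries(values=x, dt=dt, missing_mask=mask, label="signal_b")


def make_activity(spec: ActivitySpec | None = None) -> TimeSeries:
    """Non-sinusoidal activity-count record with one bout per cycle."""
    if spec is None:
        spec = ActivitySpec()
    n = int(round(spec.duration / spec.dt))
    t = spec.dt * np.arange(n)
    rng = np.random.default_rng(spec.seed)
    active = (t % spec.period) / spec.period < spec.active_fraction
    counts = rng.poisson(np.where(active, spec.bout_mean, 0.0)).astype(float)
    if spec.noise > 0:
        counts += rng.poisson(spec.noise, n)
    return TimeSeries(values=counts, dt=spec.dt, label="activity")


def make_white_noise(
    n: int, sd: float = 1.0, dt: float = 1.0, seed: int = 0
) -> TimeSeries:
    """I.i.d. Gaussian series, mean zero; the null fixture for band tests."""
    if n < 4:
        raise ValueError("need at least 4 samples")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    values = np.random.default_rng(seed).normal(0.0, sd, int(n)) if sd > 0 else np.zeros(int(n))
    return TimeSeries(values=values, dt=dt, label="white_noise")
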