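"""Ridge extraction from the CWT modulus plane.

The ridge — the path of locally maximal modulus through the time-period
plane — carries the instantaneous period, phase and amplitude of the
dominant oscillation.  Two extractors are provided: a greedy local-maximum
chaser and a stochastic "crazy climber" scheme in which annealed random
walkers accumulate an occupation density whose columnwise maxima define
the ridge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cwt import CwtResult

__all__ = ["Ridge", "ClimberParams", "ridge_local_max", "ridge_crazy_climber"]


@dataclass
class Ridge:
    """Per-time-point path through a :class:`CwtResult`.

    ``valid`` is False on columns where no ridge could be determined, in
    particular columns that are entirely inside the cone of influence when
    the transform was truncate-masked.
    """

    row_index: np.ndarray
    period: np.ndarray
    valid: np.ndarray
    method: str

    def __len__(self) -> int:
        return self.row_index.size


@dataclass(frozen=True)
class ClimberParams:
    """Crazy-climber sampler settings.

    ``n_climbers`` walkers each take ``n_moves`` steps; row moves are
    Metropolis-accepted against the modulus at temperature T, which cools
    geometrically by ``cooling`` once per block of 100 moves.
    """

    n_climbers: int = 1000
    n_moves: int = 10000
    T0: float = 1.0
    cooling: float = 0.99
    occupation_smoothing: int = 1
    seed: int = 0
    block: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.cooling < 1.0):
            raise ValueError("cooling must lie in (0, 1)")
        if min(self.n_climbers, self.n_moves, self.block) < 1:
            raise ValueError("all counts must be >= 1")


def default_max_jump(voices_per_octave: int) -> int:
    """Quarter-octave continuity window, >= 1 row."""
    return max(1, 2 * voices_per_octave // 8)


def _column_validity(result: CwtResult) -> np.ndarray:
    if result.params.edge_mode == "truncate":
        return result.edge_valid.any(axis=0)
    return np.ones(result.n, dtype=bool)


def _chain(mod: np.ndarray, start_col: int, start_row: int, max_jump: int) -> np.ndarray:
    """Grow a ridge left and right from a seed cell, limiting row jumps."""
    n_rows, n_cols = mod.shape
    rows = np.empty(n_cols, dtype=int)
    rows[start_col] = start_row
    for t in range(start_col + 1, n_cols):
        lo = max(0, rows[t - 1] - max_jump)
        hi = min(n_rows, rows[t - 1] + max_jump + 1)
        rows[t] = lo + int(np.argmax(mod[lo:hi, t]))
    for t in range(start_col - 1, -1, -1):
        lo = max(0, rows[t + 1] - max_jump)
        hi = min(n_rows, rows[t + 1] + max_jump + 1)
        rows[t] = lo + int(np.argmax(mod[lo:hi, t]))
    return rows


def ridge_local_max(result: CwtResult, max_jump: int | None = None) -> Ridge:
    """Greedy maximal-modulus ridge.

    The chain is seeded at the global modulus maximum (robust to edge
    artifacts) and grown outward, at each step taking the modulus argmax
    within ``max_jump`` rows of the previous ridge row.  Ties break toward
    the smaller row index (numpy argmax convention).
    """
    mod = result.modulus
    if max_jump is None:
        max_jump = default_max_jump(result.params.voices_per_octave)
    valid = _column_validity(result)
    if not np.any(mod > 0):
        return Ridge(
            row_index=np.zeros(result.n, dtype=int),
            period=np.full(result.n, result.periods[0]),
            valid=np.zeros(result.n, dtype=bool),
            method="local_max",
        )
    start_row, start_col = np.unravel_index(np.argmax(mod), mod.shape)
    rows = _chain(mod, int(start_col), int(start_row), max_jump)
    return Ridge(
        row_index=rows,
        period=result.periods[rows],
        valid=valid,
        method="local_max",
    )


def ridge_crazy_climber(result: CwtResult, params: ClimberParams | None = None) -> Ridge:
    """Stochastic occupation-density ridge.

    Walkers move on the (row, column) grid: column steps are always
    accepted (reflecting at the boundaries), row steps are accepted with
    probability min(1, exp((|W_new| - |W_old|)/T)).  Every visit deposits
    the local modulus into an occupation map; after optional row smoothing
    the map's columnwise maxima seed the same continuity chaining as
    :func:`ridge_local_max`.  Deterministic for a fixed seed.
    """
    if params is None:
        params = ClimberParams()
    mod = result.modulus
    n_rows, n_cols = mod.shape
    if not np.any(mod > 0):
        return ridge_local_max(result)
    rng = np.random.default_rng(params.seed)
    rows = rng.integers(0, n_rows, params.n_climbers)
    cols = rng.integers(0, n_cols, params.n_climbers)
    occupation = np.zeros_like(mod)
    T = params.T0
    for move in range(params.n_moves):
        if move and move % params.block == 0:
            T *= params.cooling
        step = np.where(rng.random(params.n_climbers) < 0.5, -1, 1)
        move_rows = rng.random(params.n_climbers) < 0.5
        # column moves: always accepted, reflecting boundaries
        new_cols = np.where(move_rows, cols, np.abs(cols + step))
        new_cols = np.where(new_cols >= n_cols, 2 * (n_cols - 1) - new_cols, new_cols)
        # row moves: Metropolis on the modulus
        new_rows = np.where(move_rows, np.abs(rows + step), rows)
        new_rows = np.where(new_rows >= n_rows, 2 * (n_rows - 1) - new_rows, new_rows)
        gain = mod[new_rows, new_cols] - mod[rows, cols]
        accept = ~move_rows | (rng.random(params.n_climbers) < np.exp(
            np.minimum(gain / max(T, 1e-12), 0.0)
        )) | (gain >= 0)
        rows = np.where(accept, new_rows, rows)
        cols = np.where(accept, new_cols, cols)
        np.add.at(occupation, (rows, cols), mod[rows, cols])
    if params.occupation_smoothing > 0:
        # triangular kernel: smooths without creating exact ties around a
        # single-row attractor
        w = params.occupation_smoothing
        kernel = np.concatenate([np.arange(1, w + 2), np.arange(w, 0, -1)]).astype(float)
        kernel /= kernel.sum()
        occupation = np.apply_along_axis(
            lambda c: np.convolve(c, kernel, mode="same"), 0, occupation
        )
    start_col = int(np.argmax(occupation.max(axis=0)))
    start_row = int(np.argmax(occupation[:, start_col]))
    max_jump = default_max_jump(result.params.voices_per_octave)
    ridge_rows = _chain(occupation, start_col, start_row, max_jump)
    return Ridge(
        row_index=ridge_rows,
        period=result.periods[ridge_rows],
        valid=_column_validity(result),
        method="crazy_climber",
    )
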