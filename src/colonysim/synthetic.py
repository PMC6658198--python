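"""Synthetic inputs with known ground truth for the analysis stage.

Reporter-style time courses (Hill-shaped or linear rises with optional
Gaussian noise) stand in for colony fluorescence curves, and hand-built
colony snapshots with prescribed core/rim patterns exercise the spatial
metrics — so the fits and metrics can be validated against parameters we
chose, without running the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .state import ColonyGrid, DARK, LIGHT, disk_mask

__all__ = [
    "ReporterTimeSeries",
    "gen_hill_course",
    "gen_linear_course",
    "gen_toy_snapshot",
]


@dataclass
class ReporterTimeSeries:
    """A (time, signal) series, optionally with its generating parameters.

    ``truth``, when present, fully determines the noiseless curve: it maps
    parameter names (including ``family``, ``noise_sd`` and ``seed``) to
    the values the generator used.
    """

    t: np.ndarray
    y: np.ndarray
    truth: Optional[dict] = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time points must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("signal values must be finite")


def hill_curve(t, n: float, K: float, fmax: float):
    """Noise-free Hill rise F(t) = Fmax·tⁿ/(Kⁿ + tⁿ), overflow-safe."""
    t = np.asarray(t, dtype=np.float64)
    out = np.zeros_like(t)
    pos = t > 0
    # 1/(1+(K/t)^n) in log space so large n cannot overflow
    logratio = n * (np.log(K) - np.log(t[pos]))
    out[pos] = fmax / (1.0 + np.exp(np.clip(logratio, -700.0, 700.0)))
    return out


def gen_hill_course(
    n: float,
    K: float,
    fmax: float,
    noise_sd: float,
    t,
    seed: int,
) -> ReporterTimeSeries:
    """Hill-shaped reporter rise with additive Gaussian noise.

    y_i = Fmax·t_iⁿ/(Kⁿ + t_iⁿ) + ε_i with ε_i ~ N(0, noise_sd²),
    truncated at zero (fluorescence cannot go negative).
    """
    if n <= 0 or K <= 0 or fmax <= 0:
        raise ValueError("Hill parameters n, K, Fmax must all be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.asarray(t, dtype=np.float64)
    y = hill_curve(t, n, K, fmax)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    y = np.maximum(y, 0.0)
    truth = {
        "family": "hill", "n": n, "K": K, "Fmax": fmax,
        "noise_sd": noise_sd, "seed": seed,
    }
    return ReporterTimeSeries(t=t, y=y, truth=truth)


def gen_linear_course(
    slope: float,
    intercept: float,
    noise_sd: float,
    t,
    seed: int,
) -> ReporterTimeSeries:
    """Linear reporter rise y = slope·t + intercept + Gaussian noise (>= 0)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.asarray(t, dtype=np.float64)
    y = slope * t + intercept
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    y = np.maximum(y, 0.0)
    truth = {
        "family": "linear", "slope": slope, "intercept": intercept,
        "noise_sd": noise_sd, "seed": seed,
    }
    return ReporterTimeSeries(t=t, y=y, truth=truth)


def gen_toy_snapshot(
    pattern: str,
    grid_size: int,
    radius: int = 20,
    core_radius: int = 10,
    rim_radius: int = 20,
) -> ColonyGrid:
    """Deterministic toy colony snapshots for spatial-metric tests.

    - ``uniform_dark``: a closed disk of DARK blocks of the given radius.
    - ``dark_core_light_rim``: DARK within ``core_radius``, LIGHT in the
      annulus out to ``rim_radius``.
    - ``checkerboard``: DARK blocks on every even-parity location of the
      whole grid, so every block has an empty orthogonal neighbor.

    All reserves are zero.
    """
    grid = ColonyGrid.blank(grid_size)
    c = grid_size // 2
    if pattern == "uniform_dark":
        if c - radius < 0 or c + radius >= grid_size:
            raise ValueError("disk radius does not fit in the grid")
        grid.state[disk_mask(grid_size, (c, c), radius)] = DARK
    elif pattern == "dark_core_light_rim":
        if core_radius > rim_radius:
            raise ValueError("core_radius must not exceed rim_radius")
        if c - rim_radius < 0 or c + rim_radius >= grid_size:
            raise ValueError("rim radius does not fit in the grid")
        rim = disk_mask(grid_size, (c, c), rim_radius)
        core = disk_mask(grid_size, (c, c), core_radius)
        grid.state[rim] = LIGHT
        grid.state[core] = DARK
    elif pattern == "checkerboard":
        yy, xx = np.indices((grid_size, grid_size))
        grid.state[(xx + yy) % 2 == 0] = DARK
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return grid
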