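"""Colony-level readouts: composition, switch timing, spatial structure,
expansion, and cooperativity / linearity fits.

The Hill fit quantifies how switch-like a rising signal is: the time
course F(t) = Fmax·tⁿ/(Kⁿ + tⁿ) is fitted by multi-start nonlinear least
squares and the exponent n read off as the cooperativity — n ≈ 1 for a
graded (hyperbolic) rise, n ≫ 1 for an abrupt, cooperative one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .state import ColonyGrid, EMPTY, LIGHT
from .synthetic import ReporterTimeSeries, hill_curve

__all__ = [
    "HillFit",
    "LinearFit",
    "RadialProfile",
    "composition_timeseries",
    "first_switch_step",
    "perimeter_emergence_step",
    "colony_extent",
    "radial_profile",
    "fit_hill",
    "fit_linear",
    "resource_peak_step",
]


@dataclass
class HillFit:
    """Fitted Hill parameters: cooperativity n, half-rise time K, plateau Fmax."""

    n: float
    K: float
    Fmax: float
    rss: float
    converged: bool


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    stderr: float = float("nan")
    zero_variance: bool = False


@dataclass
class RadialProfile:
    """Per-annulus composition around the seeding center.

    ``bin_edges`` (length n_bins+1) spans [0, max occupied radius];
    ``light_fraction`` is the LIGHT share of occupied blocks per bin (NaN
    where a bin holds no blocks, flagged in ``empty``); ``occupancy_fraction``
    is occupied blocks over lattice sites per bin; ``occupied_counts``
    partitions the occupied blocks exactly.
    """

    bin_edges: np.ndarray
    light_fraction: np.ndarray
    occupancy_fraction: np.ndarray
    occupied_counts: np.ndarray
    empty: np.ndarray


def composition_timeseries(traj) -> pd.DataFrame:
    """The per-step counts table of a trajectory (step 0 included), as a copy."""
    return traj.counts.copy()


def first_switch_step(traj):
    """Earliest step with a dark→light switch, or ``None`` if none occurred."""
    steps = [e.step for e in traj.events if e.kind == "dark_to_light"]
    return min(steps) if steps else None


def _has_perimeter_light(grid: ColonyGrid) -> bool:
    state = grid.state
    light = state == LIGHT
    if not light.any():
        return False
    # out-of-grid neighbors are not empty: pad with an occupied sentinel
    p = np.pad(state, 1, mode="constant", constant_values=1)
    empty_nb = (
        (p[:-2, 1:-1] == EMPTY)
        | (p[2:, 1:-1] == EMPTY)
        | (p[1:-1, :-2] == EMPTY)
        | (p[1:-1, 2:] == EMPTY)
    )
    return bool((light & empty_nb).any())


def perimeter_emergence_step(traj):
    """First snapshot step (after step 0) with a LIGHT block on the colony rim.

    "On the rim" means having at least one EMPTY von Neumann neighbor,
    the same adjacency the division rule uses. The seeding snapshot is
    excluded because its light blocks are placed at random rather than
    having emerged; returns ``None`` if no later snapshot qualifies.
    """
    for t, grid, _ in traj.snapshots:
        if t == 0:
            continue
        if _has_perimeter_light(grid):
            return t
    return None


def _radii(grid: ColonyGrid, center=None):
    occ = np.argwhere(grid.state != EMPTY)
    if center is None:
        c = grid.grid_size // 2
        center = (c, c)
    if len(occ) == 0:
        return occ, np.zeros(0)
    d = np.hypot(occ[:, 0] - center[0], occ[:, 1] - center[1])
    return occ, d


def colony_extent(grid: ColonyGrid, center=None) -> tuple[int, float, float]:
    """(occupied count, max radius from the seeding center, diameter).

    Radii are Euclidean distances in grid lengths. An empty grid gives
    (0, 0, 0); a single block at the center gives (1, 0, 0).
    """
    occ, d = _radii(grid, center)
    if len(occ) == 0:
        return 0, 0.0, 0.0
    r = float(d.max())
    return len(occ), r, 2.0 * r


def radial_profile(grid: ColonyGrid, n_bins: int, center=None) -> RadialProfile:
    """Bin occupied blocks by distance from the seeding center.

    Bins are ``n_bins`` equal-width annuli spanning [0, max radius]
    (right-closed at the outer edge, so the bins partition the occupied
    blocks exactly).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    occ, d = _radii(grid, center)
    if len(occ) == 0:
        raise ValueError("radial_profile needs at least one occupied block")
    rmax = max(float(d.max()), 1e-12)
    edges = np.linspace(0.0, rmax, n_bins + 1)
    total, _ = np.histogram(d, bins=edges)
    is_light = grid.state[occ[:, 0], occ[:, 1]] == LIGHT
    light, _ = np.histogram(d[is_light], bins=edges)

    # lattice sites available per annulus, for the occupancy fraction
    if center is None:
        c = grid.grid_size // 2
        center = (c, c)
    yy, xx = np.indices(grid.state.shape)
    all_d = np.hypot(yy - center[0], xx - center[1]).ravel()
    sites, _ = np.histogram(all_d[all_d <= rmax], bins=edges)

    empty_bins = total == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        light_frac = np.where(empty_bins, np.nan, light / np.maximum(total, 1))
        occ_frac = np.where(sites > 0, total / np.maximum(sites, 1), 0.0)
    return RadialProfile(
        bin_edges=edges,
        light_fraction=light_frac,
        occupancy_fraction=occ_frac,
        occupied_counts=total,
        empty=empty_bins,
    )


_HILL_STARTS = (0.5, 1.0, 2.0, 4.0, 8.0)
_HILL_N_MAX = 200.0


def fit_hill(series: ReporterTimeSeries) -> HillFit:
    """Least-squares Hill fit F(t) = Fmax·tⁿ/(Kⁿ + tⁿ) to a rise curve.

    Time is the dose variable; points at t <= 0 are dropped (the Hill form
    is identically 0 there). The signal is normalized to its maximum
    before fitting and the plateau rescaled back afterwards. Multiple
    starting exponents guard against local minima; if no start converges
    the best-guess parameters are returned with ``converged=False``.
    Requires at least five positive-time points and a non-zero signal.

    The fit is constrained to an identifiable region: the normalized
    plateau may not exceed twice the observed maximum and the half-rise
    time K must lie within ten times the observed window — without these
    bounds an unsaturated curve degenerates into a power law with
    K and Fmax running away together.
    """
    keep = series.t > 0
    t = series.t[keep]
    y = series.y[keep]
    if len(t) < 5:
        raise ValueError("fit_hill needs at least 5 time points with t > 0")
    ymax = float(y.max())
    if ymax <= 0:
        raise ValueError("fit_hill needs a non-zero signal")
    yn = y / ymax

    # initial K: time at which the normalized signal first crosses 1/2
    above = np.nonzero(yn >= 0.5)[0]
    k0 = float(t[above[0]]) if len(above) else float(np.median(t))
    k0 = max(k0, float(t[0]) * 0.5)

    best = None
    for n0 in _HILL_STARTS:
        try:
            popt, _ = optimize.curve_fit(
                hill_curve,
                t,
                yn,
                p0=(n0, k0, 1.0),
                bounds=((1e-3, 1e-9, 1e-9),
                        (_HILL_N_MAX, 10.0 * float(t.max()), 2.0)),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((hill_curve(t, *popt) - yn) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return HillFit(n=float("nan"), K=k0, Fmax=ymax, rss=float("inf"),
                       converged=False)
    (n, K, fmax_n), rss = best
    return HillFit(
        n=float(n),
        K=float(K),
        Fmax=float(fmax_n * ymax),
        rss=float(rss * ymax * ymax),
        converged=True,
    )


def fit_linear(series: ReporterTimeSeries) -> LinearFit:
    """Ordinary least squares y = slope·t + intercept with r² = 1 − RSS/TSS.

    A zero-variance response is fitted as a flat line with r² reported as
    0 by convention (flagged); zero variance in t is an error.
    """
    t, y = series.t, series.y
    if len(t) < 3:
        raise ValueError("fit_linear needs at least 3 points")
    if np.ptp(t) == 0:
        raise ValueError("fit_linear needs variance in t")
    if np.ptp(y) == 0:
        warnings.warn("zero-variance response; r² set to 0 by convention")
        return LinearFit(slope=0.0, intercept=float(y[0]), r_squared=0.0,
                         stderr=0.0, zero_variance=True)
    res = stats.linregress(t, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        stderr=float(res.stderr),
    )


def resource_peak_step(traj) -> int:
    """Step at which the total external resource is largest (first on ties)."""
    counts = traj.counts
    i = int(np.argmax(counts["total_resource"].to_numpy()))
    return int(counts["step"].iloc[i])
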