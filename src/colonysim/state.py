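"""Lattice state: the colony occupancy grid, the resource field, and seeding.

The colony lives on a square integer lattice. Each location is empty or
holds one "cell block" (~100 yeast cells at 50 µm per grid length) that is
entirely dark (gluconeogenic, resource-producing) or entirely light
(resource-consuming, fast-dividing). Occupied blocks carry internal
amino-acid and resource reserves; the external shared-resource
concentration is a separate real-valued field over the same lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .params import ModelParams

__all__ = [
    "EMPTY",
    "DARK",
    "LIGHT",
    "EVENT_KINDS",
    "AA_SATURATING",
    "ColonyGrid",
    "ResourceField",
    "TransitionEvent",
    "seed_colony",
    "count_states",
    "disk_mask",
]

EMPTY, DARK, LIGHT = 0, 1, 2

EVENT_KINDS = ("dark_to_light", "light_to_dark", "division_dark", "division_light")

#: Initial level of the explicit amino-acid field in the reverse-sharing
#: variant: large enough to be effectively inexhaustible, so dark-block
#: growth is never amino-acid limited.
AA_SATURATING = 1.0e6


@dataclass
class ColonyGrid:
    """Occupancy lattice plus per-block internal reserves.

    ``state`` holds the codes EMPTY/DARK/LIGHT; ``aa_reserve`` and
    ``res_reserve`` are same-shaped float arrays that are meaningful (and
    non-negative) only where ``state != EMPTY``, and identically zero at
    empty locations.
    """

    state: np.ndarray
    aa_reserve: np.ndarray
    res_reserve: np.ndarray

    @classmethod
    def blank(cls, grid_size: int) -> "ColonyGrid":
        """An all-empty grid of the given side length."""
        shape = (grid_size, grid_size)
        return cls(
            state=np.zeros(shape, dtype=np.uint8),
            aa_reserve=np.zeros(shape, dtype=np.float64),
            res_reserve=np.zeros(shape, dtype=np.float64),
        )

    @property
    def grid_size(self) -> int:
        return self.state.shape[0]

    def copy(self) -> "ColonyGrid":
        return ColonyGrid(
            self.state.copy(), self.aa_reserve.copy(), self.res_reserve.copy()
        )

    def check(self) -> None:
        """Verify the reserve/occupancy invariants; raise ValueError if broken."""
        occupied = self.state != EMPTY
        if np.any(self.aa_reserve[~occupied] != 0) or np.any(
            self.res_reserve[~occupied] != 0
        ):
            raise ValueError("empty locations must carry no reserves")
        if np.any(self.aa_reserve < 0) or np.any(self.res_reserve < 0):
            raise ValueError("reserves must be non-negative")
        if not np.isin(self.state, (EMPTY, DARK, LIGHT)).all():
            raise ValueError("state codes must be EMPTY, DARK or LIGHT")


@dataclass
class ResourceField:
    """External concentration fields over the lattice.

    ``u`` is the diffusing shared resource (trehalose in the biology).
    ``aa_field`` is the explicit amino-acid field used only by the
    reverse-sharing variant; it is ``None`` otherwise.
    """

    u: np.ndarray
    aa_field: Optional[np.ndarray] = None

    def copy(self) -> "ResourceField":
        return ResourceField(
            self.u.copy(), None if self.aa_field is None else self.aa_field.copy()
        )

    def check(self) -> None:
        if np.any(self.u < 0):
            raise ValueError("resource concentration must be non-negative")


@dataclass(frozen=True)
class TransitionEvent:
    """One recorded state change: a switch or a division, with step and site."""

    step: int
    location: tuple[int, int]
    kind: str

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


def disk_mask(grid_size: int, center: tuple[int, int], radius: int) -> np.ndarray:
    """Boolean mask of the closed lattice disk (x-cx)² + (y-cy)² <= r²."""
    yy, xx = np.ogrid[:grid_size, :grid_size]
    cx, cy = center
    return (xx - cy) ** 2 + (yy - cx) ** 2 <= radius * radius


def seed_colony(
    params: ModelParams, rng: np.random.Generator
) -> tuple[ColonyGrid, ResourceField]:
    """Construct the initial colony: a dark disk with a sprinkling of lights.

    Every lattice point within ``init_radius`` (closed disk, Euclidean
    metric) of the grid center is occupied — 1257 locations at the default
    radius of 20. ``round(init_light_fraction * n_occupied)`` of them,
    chosen uniformly at random, start LIGHT; the rest start DARK. All
    internal reserves and the external resource start at zero.
    """
    params.validate()
    n = params.grid_size
    r = params.init_radius
    c = n // 2
    if c - r < 0 or c + r >= n:
        raise ValueError(
            f"seeding disk of radius {r} does not fit in a {n}x{n} grid"
        )
    grid = ColonyGrid.blank(n)
    mask = disk_mask(n, (c, c), r)
    grid.state[mask] = DARK

    occ = np.argwhere(mask)
    n_light = int(round(params.init_light_fraction * len(occ)))
    if n_light > 0:
        pick = rng.choice(len(occ), size=n_light, replace=False)
        grid.state[occ[pick, 0], occ[pick, 1]] = LIGHT

    field = ResourceField(u=np.zeros((n, n), dtype=np.float64))
    if params.variant == "reverse_sharing":
        field.aa_field = np.full((n, n), AA_SATURATING, dtype=np.float64)
    return grid, field


def count_states(grid: ColonyGrid) -> tuple[int, int, int]:
    """Return ``(n_dark, n_light, n_occupied)`` for the lattice."""
    n_dark = int(np.count_nonzero(grid.state == DARK))
    n_light = int(np.count_nonzero(grid.state == LIGHT))
    return n_dark, n_light, n_dark + n_light
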