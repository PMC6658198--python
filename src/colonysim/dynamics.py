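"""One time step of the colony model: per-block stochastic rules plus diffusion.

Each step sweeps every occupied block once, in a fresh random permutation,
applying the dark- or light-block rule list, and then advances the external
resource field by one explicit FTCS (Forward Time Central Space) diffusion
update. Dark blocks switch to light when the local resource reaches the
threshold S, otherwise produce R units of resource, take up C units of
ambient amino acids, and may divide; light blocks internalize all local
resource (or revert to dark when there is none to speak of) and may divide.

Rule ordering within a block follows the published lists exactly: the
switching check precedes that step's production, and a block that changes
state takes no further action until the next step. Light-block uptake is
bounded: every cell block consumes C units per step as maintenance, and a
light block additionally internalizes local resource only up to the 1.0
units it needs to divide — a sated block lets the rest flow past. This
bounded store is what lets the dark interior's production accumulate into
a halo around the colony, ignite threshold switching at the rim, and fuel
the rapid peripheral expansion of light blocks; unbounded uptake would
lock the colony into a starved interior standoff instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .params import ModelParams, VARIANTS
from .state import (
    ColonyGrid,
    DARK,
    EMPTY,
    LIGHT,
    ResourceField,
    TransitionEvent,
)

__all__ = [
    "StepReport",
    "stability_limit",
    "apply_variant",
    "ftcs_step",
    "select_division_site",
    "update_dark_block",
    "update_light_block",
    "step",
]


@dataclass
class StepReport:
    """Bookkeeping for one step: transition events and resource turnover."""

    events: list = dc_field(default_factory=list)
    produced: float = 0.0  # resource units added to the field this step
    consumed: float = 0.0  # resource units internalized by light blocks


def stability_limit() -> float:
    """Von Neumann stability bound for the 2-D FTCS scheme, ΔL²/(4ΔT).

    With the model's unit time step and unit grid length this is 0.25:
    diffusion constants above it make the explicit update unstable.
    """
    return 0.25


def apply_variant(params: ModelParams) -> ModelParams:
    """Return parameters with the published overrides for the chosen variant.

    - ``no_sharing``: dark blocks produce nothing (R = 0).
    - ``no_switching``: dark blocks never switch (p = 0).
    - ``reverse_sharing``: R = 0, and light blocks instead add R' to an
      explicit amino-acid field at their own location.
    - ``no_threshold``: S = 0 (switching gated only by chance), and light
      blocks cannot revert to dark.
    - ``linear_switching``: S = 0 and the per-step switch probability is
      min(m·u, 1), linear in the locally available resource.
    """
    params.validate()
    v = params.variant
    if v == "wildtype":
        return params.replace()
    if v == "no_sharing":
        return params.replace(production=0.0)
    if v == "no_switching":
        return params.replace(switch_prob=0.0)
    if v == "reverse_sharing":
        return params.replace(production=0.0)
    if v == "no_threshold":
        return params.replace(switch_threshold=0.0, switchback_enabled=False)
    if v == "linear_switching":
        return params.replace(switch_threshold=0.0, switchback_enabled=False)
    raise ValueError(f"unknown variant {v!r}; expected one of {VARIANTS}")


def ftcs_step(field: ResourceField, params: ModelParams) -> ResourceField:
    """Advance the resource field by one explicit FTCS diffusion update.

    u'(x,y) = u + D·(u_left + u_right + u_down + u_up − 4u) with unit time
    step and grid length. Edges are no-flux (reflecting), so the total
    resource on the plate is conserved by diffusion alone. The field is
    updated in place and returned.
    """
    d = params.diffusion
    if d > stability_limit():
        raise ValueError(
            f"diffusion {d} exceeds the FTCS stability limit {stability_limit()}"
        )
    if d < 0:
        raise ValueError(f"diffusion must be >= 0, got {d}")
    if d == 0.0:
        return field
    u = field.u
    p = np.pad(u, 1, mode="edge")
    lap = p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * u
    u += d * lap
    return field


def select_division_site(
    location: tuple[int, int], grid: ColonyGrid, rng: np.random.Generator
):
    """Pick the empty von Neumann neighbor a daughter block should occupy.

    Among empty orthogonal neighbors, prefers the one with the most
    occupied orthogonal neighbors of its own (crowded pockets fill first),
    breaking ties uniformly at random. Returns ``None`` if no empty
    neighbor exists; locations outside the grid are neither empty nor
    occupied.
    """
    x, y = location
    state = grid.state
    n = state.shape[0]
    best: list[tuple[int, int]] = []
    best_count = -1
    for nx, ny in ((x - 1, y), (x + 1, y), (x, y - 1), (x, y + 1)):
        if not (0 <= nx < n and 0 <= ny < n) or state[nx, ny] != EMPTY:
            continue
        count = 0
        for mx, my in ((nx - 1, ny), (nx + 1, ny), (nx, ny - 1), (nx, ny + 1)):
            if 0 <= mx < n and 0 <= my < n and state[mx, my] != EMPTY:
                count += 1
        if count > best_count:
            best = [(nx, ny)]
            best_count = count
        elif count == best_count:
            best.append((nx, ny))
    if not best:
        return None
    if len(best) == 1:
        return best[0]
    return best[int(rng.integers(len(best)))]


def _divide(grid, location, site, daughter_state):
    # Mother stays put; daughter inherits her state; both internal
    # reserves are halved between the two so no mass appears or vanishes.
    x, y = location
    sx, sy = site
    grid.state[sx, sy] = daughter_state
    half_aa = grid.aa_reserve[x, y] * 0.5
    half_res = grid.res_reserve[x, y] * 0.5
    grid.aa_reserve[x, y] = half_aa
    grid.aa_reserve[sx, sy] = half_aa
    grid.res_reserve[x, y] = half_res
    grid.res_reserve[sx, sy] = half_res


def update_dark_block(
    location: tuple[int, int],
    grid: ColonyGrid,
    field: ResourceField,
    params: ModelParams,
    rng: np.random.Generator,
    report: StepReport | None = None,
    t: int = 0,
) -> StepReport:
    """Apply the dark-block rule list at one location for one step.

    In order: (a) if the local resource has reached the threshold S, switch
    to LIGHT with probability p (and do nothing else this step); (b) while
    still dark, add R units of resource at this location; (c) take up C
    units of the ambient amino acids; (d) with the internal amino-acid
    reserve at or above the division minimum, divide with probability
    g_dark into the preferred empty neighbor, halving reserves between
    mother and daughter.
    """
    if report is None:
        report = StepReport()
    x, y = location
    if grid.state[x, y] != DARK:
        raise ValueError(f"update_dark_block called on non-DARK location {location}")
    u = field.u[x, y]

    if u >= params.switch_threshold:
        if params.variant == "linear_switching":
            p_switch = min(params.linear_slope * u, 1.0)
        else:
            p_switch = params.switch_prob
        if p_switch > 0.0 and rng.random() < p_switch:
            grid.state[x, y] = LIGHT
            # amino-acid reserve is retained but frozen; the light state
            # starts with whatever resource reserve the block already had
            report.events.append(TransitionEvent(t, (x, y), "dark_to_light"))
            return report

    if params.production > 0.0:
        field.u[x, y] = u + params.production
        report.produced += params.production

    grid.aa_reserve[x, y] += params.consumption

    if grid.aa_reserve[x, y] >= params.division_reserve and rng.random() < params.g_dark:
        site = select_division_site((x, y), grid, rng)
        if site is not None:
            _divide(grid, (x, y), site, DARK)
            report.events.append(TransitionEvent(t, (x, y), "division_dark"))
    return report


def update_light_block(
    location: tuple[int, int],
    grid: ColonyGrid,
    field: ResourceField,
    params: ModelParams,
    rng: np.random.Generator,
    report: StepReport | None = None,
    t: int = 0,
) -> StepReport:
    """Apply the light-block rule list at one location for one step.

    In order: (a) if at least C units of resource are present locally,
    consume this step's maintenance ration C and internalize as much of
    the remainder as the block's bounded store can hold (up to the
    division requirement of 1.0 unit); any surplus stays external and
    keeps diffusing. (b) If less than C is present, the light state
    cannot be sustained: when switch-back is enabled the block reverts to
    DARK (keeping both reserves) and stops for this step. (c) With the
    internal resource reserve at the division minimum, divide with
    probability g_light, halving reserves between mother and daughter.
    In the reverse-sharing variant the block also deposits R' units onto
    the amino-acid field at its location.
    """
    if report is None:
        report = StepReport()
    x, y = location
    if grid.state[x, y] != LIGHT:
        raise ValueError(f"update_light_block called on non-LIGHT location {location}")

    if params.variant == "reverse_sharing" and field.aa_field is not None:
        field.aa_field[x, y] += params.reverse_production

    u = field.u[x, y]
    c = params.consumption
    if u >= c:
        # pay this step's maintenance from the location, then internalize
        # as much of the remainder as the block can store
        room = max(params.division_reserve - grid.res_reserve[x, y], 0.0)
        uptake = min(u - c, room)
        grid.res_reserve[x, y] += uptake
        field.u[x, y] = u - c - uptake
        report.consumed += c + uptake
    elif params.switchback_enabled:
        # resource absent at this location: the light state is not sustained
        grid.state[x, y] = DARK
        report.events.append(TransitionEvent(t, (x, y), "light_to_dark"))
        return report

    if grid.res_reserve[x, y] >= params.division_reserve and rng.random() < params.g_light:
        site = select_division_site((x, y), grid, rng)
        if site is not None:
            _divide(grid, (x, y), site, LIGHT)
            report.events.append(TransitionEvent(t, (x, y), "division_light"))
    return report


def step(
    grid: ColonyGrid,
    field: ResourceField,
    params: ModelParams,
    rng: np.random.Generator,
    t: int,
) -> StepReport:
    """Advance the whole model by one time step.

    Sweeps the blocks occupied at the start of the step in a fresh random
    permutation (daughters born during the sweep first act next step),
    then applies exactly one FTCS diffusion update to the resource field.
    Expects parameters that already carry their variant overrides (see
    :func:`apply_variant`); :mod:`colonysim.runner` does this for you.
    """
    report = StepReport()
    occupied = np.argwhere(grid.state != EMPTY)
    if len(occupied):
        order = rng.permutation(len(occupied))
        state = grid.state
        for i in order:
            x, y = int(occupied[i, 0]), int(occupied[i, 1])
            s = state[x, y]
            if s == DARK:
                update_dark_block((x, y), grid, field, params, rng, report, t)
            else:
                update_light_block((x, y), grid, field, params, rng, report, t)
    ftcs_step(field, params)
    return report
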