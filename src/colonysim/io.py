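"""Plain-text file formats and rendering.

Everything the simulator writes is diff-able text: grid snapshots and the
resource field as CSV matrices with '#'-prefixed metadata headers, per-step
counts and the event log as ordinary CSV tables, parameters as flat
key=value config, reporter series as two-column CSV with their generating
truth recorded in the header. PNG rendering (one pixel per grid location)
is the only binary output.
"""

from __future__ import annotations

import ast
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .params import ModelParams, format_config, params_digest, parse_config
from .runner import COUNT_COLUMNS, SimulationTrajectory
from .state import ColonyGrid, DARK, EMPTY, LIGHT, ResourceField, TransitionEvent
from .synthetic import ReporterTimeSeries

__all__ = [
    "write_snapshot",
    "read_snapshot",
    "write_timeseries",
    "read_timeseries",
    "write_events",
    "read_events",
    "write_reporter_series",
    "read_reporter_series",
    "render_png",
    "save_trajectory",
    "load_trajectory",
]

FORMAT_VERSION = 1
VALID_CODES = frozenset((EMPTY, DARK, LIGHT))

#: Default render palette (RGB): empty agar, dense dark blocks, light blocks.
DEFAULT_PALETTE = {
    EMPTY: (15, 15, 20),
    DARK: (140, 90, 30),
    LIGHT: (245, 240, 200),
}


def _resource_path(path: Path) -> Path:
    return path.with_name(path.stem + ".resource" + path.suffix)


def write_snapshot(
    path,
    grid: ColonyGrid,
    field: ResourceField | None = None,
    step: int = 0,
    seed: int = 0,
    params: ModelParams | None = None,
) -> Path:
    """Write a grid snapshot (and companion resource file) as headered CSV.

    The body is ``grid_size`` rows of comma-separated codes (0 empty,
    1 dark, 2 light). The resource field, if given, goes to a sibling
    ``<stem>.resource<suffix>`` file at full double precision.
    """
    path = Path(path)
    n = grid.grid_size
    header = [
        f"# format_version={FORMAT_VERSION}",
        f"# step={step}",
        f"# seed={seed}",
        f"# grid_size={n}",
    ]
    if params is not None:
        header.append(f"# params_digest={params_digest(params)}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, grid.state, fmt="%d", delimiter=",")
    if field is not None:
        with open(_resource_path(path), "w") as fh:
            fh.write("\n".join(header) + "\n")
            np.savetxt(fh, field.u, fmt="%.17g", delimiter=",")
    return path


def _read_headered_csv(path: Path):
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            rows.append(line.split(","))
    if "grid_size" not in meta:
        raise ValueError(f"{path}: malformed header, missing grid_size")
    n = int(meta["grid_size"])
    if len(rows) != n or any(len(r) != n for r in rows):
        raise ValueError(f"{path}: body dimensions do not match grid_size={n}")
    return meta, rows


def read_snapshot(path) -> tuple[ColonyGrid, ResourceField | None, dict]:
    """Read a snapshot written by :func:`write_snapshot`.

    Returns the grid (reserves zero — they are not persisted), the
    resource field if its companion file exists, and the header metadata.
    """
    path = Path(path)
    meta, rows = _read_headered_csv(path)
    state = np.array([[int(v) for v in r] for r in rows], dtype=np.uint8)
    if not set(np.unique(state)) <= VALID_CODES:
        bad = sorted(set(np.unique(state)) - VALID_CODES)
        raise ValueError(f"{path}: illegal state codes {bad}")
    grid = ColonyGrid.blank(state.shape[0])
    grid.state = state
    field = None
    rpath = _resource_path(path)
    if rpath.exists():
        _, rrows = _read_headered_csv(rpath)
        u = np.array([[float(v) for v in r] for r in rrows], dtype=np.float64)
        if np.any(u < 0):
            raise ValueError(f"{rpath}: resource values must be non-negative")
        field = ResourceField(u=u)
    return grid, field, meta


def write_timeseries(path, counts: pd.DataFrame) -> Path:
    """Write the per-step counts table as CSV (step 0 row included)."""
    path = Path(path)
    missing = set(COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns {sorted(missing)}")
    counts.loc[:, list(COUNT_COLUMNS)].to_csv(path, index=False)
    return path


def read_timeseries(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_events(path, events) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("step,x,y,kind\n")
        for e in events:
            fh.write(f"{e.step},{e.location[0]},{e.location[1]},{e.kind}\n")
    return path


def read_events(path) -> list[TransitionEvent]:
    df = pd.read_csv(path)
    return [
        TransitionEvent(int(r.step), (int(r.x), int(r.y)), str(r.kind))
        for r in df.itertuples()
    ]


def write_reporter_series(path, series: ReporterTimeSeries) -> Path:
    """Two-column CSV; the generating truth, if any, rides in a '#' header."""
    path = Path(path)
    with open(path, "w") as fh:
        if series.truth is not None:
            fh.write(f"# truth={json.dumps(series.truth)}\n")
        fh.write("t,y\n")
        for t, y in zip(series.t, series.y):
            fh.write(f"{float(t)!r},{float(y)!r}\n")
    return path


def read_reporter_series(path) -> ReporterTimeSeries:
    path = Path(path)
    truth = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            body = first.lstrip("#").strip()
            if body.startswith("truth="):
                truth = json.loads(body[len("truth="):])
            rest = fh.read()
        else:
            rest = first + fh.read()
    from io import StringIO

    df = pd.read_csv(StringIO(rest), float_precision="round_trip")
    return ReporterTimeSeries(
        t=df["t"].to_numpy(), y=df["y"].to_numpy(), truth=truth
    )


def render_png(grid: ColonyGrid, path, palette: dict | None = None) -> Path:
    """Render a snapshot as a PNG, one pixel per lattice location."""
    palette = DEFAULT_PALETTE if palette is None else palette
    n = grid.grid_size
    rgb = np.zeros((n, n, 3), dtype=np.uint8)
    for code, color in palette.items():
        rgb[grid.state == code] = color
    path = Path(path)
    Image.fromarray(rgb, mode="RGB").save(path)
    return path


def save_trajectory(outdir, traj: SimulationTrajectory) -> Path:
    """Write a trajectory as a directory of text artifacts.

    ``config.txt`` (parameters), ``counts.csv``, ``events.csv`` and one
    ``snapshot_NNNN.csv`` (+ resource companion) per stored snapshot.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.txt").write_text(format_config(traj.params))
    write_timeseries(outdir / "counts.csv", traj.counts)
    write_events(outdir / "events.csv", traj.events)
    for t, grid, field in traj.snapshots:
        write_snapshot(
            outdir / f"snapshot_{t:04d}.csv",
            grid,
            field,
            step=t,
            seed=traj.seed,
            params=traj.params,
        )
    return outdir


def load_trajectory(outdir) -> SimulationTrajectory:
    """Reload a trajectory directory written by :func:`save_trajectory`.

    Snapshot grids come back with zeroed reserves (not persisted); counts
    and events are exact.
    """
    outdir = Path(outdir)
    params = parse_config((outdir / "config.txt").read_text())
    counts = read_timeseries(outdir / "counts.csv")
    events = read_events(outdir / "events.csv")
    snapshots = []
    for snap in sorted(outdir.glob("snapshot_*.csv")):
        if ".resource" in snap.name:
            continue
        grid, field, meta = read_snapshot(snap)
        snapshots.append((int(meta.get("step", 0)), grid, field))
    snapshots.sort(key=lambda s: s[0])
    return SimulationTrajectory(
        params=params,
        seed=params.seed,
        counts=counts,
        snapshots=snapshots,
        events=events,
    )
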