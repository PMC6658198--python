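"""Model parameters, validation, and flat key=value configuration handling.

All rates are expressed in grid units: one time step is one unit of time
(12 min of real time by default) and one grid length is one unit of length
(50 µm by default). Resource and amino-acid amounts are in the arbitrary
"reserve" units of the model, where 1.0 unit is the minimum internal
reserve a cell block needs in order to divide.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, fields

__all__ = [
    "VARIANTS",
    "ModelParams",
    "default_params",
    "parse_config",
    "format_config",
    "params_digest",
]

#: The six published rule sets: the wild-type model and its five controls.
VARIANTS = (
    "wildtype",
    "no_sharing",
    "no_switching",
    "reverse_sharing",
    "no_threshold",
    "linear_switching",
)


@dataclass
class ModelParams:
    """Complete parameterization of one colony simulation.

    Defaults are the wild-type values: slow dark-block division
    (``g_dark = 0.01`` per step), fast light-block division
    (``g_light = 0.04`` per step), resource production ``R = 0.07``
    units/step per dark block, consumption ``C = 0.05`` units/step,
    switching threshold ``S = 3.0`` units with switch probability
    ``p = 0.5``, and resource diffusion ``D = 0.24`` grid-lengths²/step
    (just below the FTCS stability limit of 0.25).
    """

    grid_size: int = 250
    init_radius: int = 20
    init_light_fraction: float = 0.02
    g_dark: float = 0.01
    g_light: float = 0.04
    switch_threshold: float = 3.0
    production: float = 0.07
    consumption: float = 0.05
    division_reserve: float = 1.0
    switch_prob: float = 0.5
    diffusion: float = 0.24
    n_steps: int = 750
    dt_minutes: float = 12.0
    dx_micron: float = 50.0
    variant: str = "wildtype"
    linear_slope: float = 0.5
    reverse_production: float = 0.07
    switchback_enabled: bool = True
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` on any out-of-range or inconsistent field."""
        for name in ("g_dark", "g_light", "switch_prob", "init_light_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if not 0.0 <= self.diffusion <= 0.25:
            raise ValueError(
                f"diffusion must lie in [0, 0.25] (FTCS stability), got {self.diffusion}"
            )
        for name in (
            "switch_threshold",
            "production",
            "consumption",
            "division_reserve",
            "reverse_production",
            "linear_slope",
        ):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.grid_size < 1:
            raise ValueError(f"grid_size must be positive, got {self.grid_size}")
        if self.init_radius < 0:
            raise ValueError(f"init_radius must be >= 0, got {self.init_radius}")
        if self.grid_size <= 2 * self.init_radius:
            raise ValueError(
                f"grid_size ({self.grid_size}) must exceed twice init_radius "
                f"({self.init_radius}) so the seeded disk fits"
            )
        if self.n_steps < 0:
            raise ValueError(f"n_steps must be >= 0, got {self.n_steps}")
        if self.dt_minutes <= 0 or self.dx_micron <= 0:
            raise ValueError("dt_minutes and dx_micron must be positive")
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)


def default_params() -> ModelParams:
    """Wild-type defaults: the published parameter table plus geometry.

    250 × 250 grid seeded with a radius-20 disk (1257 blocks, 2% light),
    run for 750 steps of 12 min each (150 h, ~6 days of colony growth).
    """
    return ModelParams()


_BOOL_STRINGS = {"true": True, "false": False, "1": True, "0": False,
                 "yes": True, "no": False}


def _parse_value(name: str, ftype: type, raw: str):
    if ftype is bool:
        try:
            return _BOOL_STRINGS[raw.strip().lower()]
        except KeyError:
            raise ValueError(f"config key {name}: cannot parse {raw!r} as boolean")
    try:
        return ftype(raw.strip())
    except ValueError:
        raise ValueError(
            f"config key {name}: cannot parse {raw!r} as {ftype.__name__}"
        ) from None


def parse_config(text: str) -> ModelParams:
    """Parse a flat ``key = value`` configuration into :class:`ModelParams`.

    One assignment per line; blank lines and ``#`` comments are ignored.
    Keys are the :class:`ModelParams` field names; unknown keys and
    unparsable values are errors. Omitted keys keep their defaults.
    """
    ftypes = {f.name: f.type for f in fields(ModelParams)}
    # dataclass field .type may be a string under `from __future__ import annotations`
    resolved = {"int": int, "float": float, "str": str, "bool": bool}
    values = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected key=value, got {line!r}")
        key, raw = (part.strip() for part in line.split("=", 1))
        if key not in ftypes:
            raise ValueError(f"config line {lineno}: unknown key {key!r}")
        ftype = ftypes[key]
        if isinstance(ftype, str):
            ftype = resolved[ftype]
        values[key] = _parse_value(key, ftype, raw)
    params = ModelParams(**values)
    params.validate()
    return params


def format_config(params: ModelParams) -> str:
    """Render parameters as the flat key=value text accepted by parse_config."""
    lines = ["# colonysim run configuration"]
    for f in fields(ModelParams):
        v = getattr(params, f.name)
        if isinstance(v, bool):
            v = "true" if v else "false"
        elif isinstance(v, float):
            v = repr(v)
        lines.append(f"{f.name} = {v}")
    return "\n".join(lines) + "\n"


def params_digest(params: ModelParams) -> str:
    """Short stable digest of a parameter set, for snapshot headers."""
    return hashlib.sha256(format_config(params).encode()).hexdigest()[:12]
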