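"""Configuration model and loader.

All geometric and numbering conventions of the generator live here as
dataclass defaults; an optional YAML file can override any subset of them.
Unknown keys are rejected loudly (no silent typos) and every value is
validated against its physical range before use.

Units: lengths in cm, densities in g/cm^3, energies in MeV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class HoleConfig:
    """Drill-hole layout of a brick.

    ``source_offsets`` are (dx, dy) offsets of the four rod-source drill
    holes from the centre of the 16.5 cm x 11 cm front face.  The defaults
    put every hole axis exactly on a lattice-cell centre (x in {4.125,
    12.375}, y in {4.125, 6.875} cm in brick-local coordinates), so a rod
    source never straddles two lattice columns.  The real phantom's drill
    positions are not public; these are package conventions.
    """

    source_offsets: tuple[tuple[float, float], ...] = (
        (-4.125, -1.375),
        (-4.125, 1.375),
        (4.125, -1.375),
        (4.125, 1.375),
    )
    source_radius: float = 0.4
    #: None means "through hole": depth equals the brick thickness.
    source_depth: float | None = None
    connector_radius: float = 0.3
    connector_depth: float = 1.0


@dataclass(frozen=True)
class RodConfig:
    """Rod-source geometry: a cylinder inserted flush with the front face.

    The active section spans [0, thickness - plug_length] along the hole
    axis; the inactive plug fills the remainder.  With the default
    ``plug_length = 0`` the half-brick active length is exactly half the
    full-brick one, so the 1 : 1/2 per-source probability rule coincides
    with active-length-proportional weighting.
    """

    radius: float = 0.35
    plug_length: float = 0.0


@dataclass(frozen=True)
class MaterialConfig:
    polyethylene_density: float = 0.95
    air_density: float = 1.205e-3


@dataclass(frozen=True)
class NumberingConfig:
    """Deterministic id bases for the emitted deck (documented convention)."""

    world_cell: int = 1
    outside_cell: int = 2
    graveyard_cell: int = 3
    background_cells: tuple[int, int] = (5, 6)
    lattice_cell: int = 10
    lattice_universe: int = 10
    background_universe: int = 5
    world_surface: int = 1
    container_surface: int = 2
    element_surface: int = 3
    brick_universe_base: int = 50
    template_cell_base: int = 100
    template_cell_stride: int = 20
    surface_base: int = 1000
    surface_stride: int = 100
    segment_universe_base: int = 200
    segment_universe_stride: int = 200
    segment_cell_base: int = 10000
    segment_cell_stride: int = 200
    tr_base: int = 900
    material_polyethylene: int = 1
    material_air: int = 2


@dataclass(frozen=True)
class PhantomConfig:
    """Top-level configuration of the deck generator."""

    full_dims: tuple[float, float, float] = (16.5, 11.0, 5.5)
    half_dims: tuple[float, float, float] = (16.5, 11.0, 2.75)
    holes: HoleConfig = field(default_factory=HoleConfig)
    rod: RodConfig = field(default_factory=RodConfig)
    materials: MaterialConfig = field(default_factory=MaterialConfig)
    numbering: NumberingConfig = field(default_factory=NumberingConfig)
    #: LDraw units per cm (1 LDU = 0.4 mm, i.e. 25 LDU per cm).
    ldraw_scale: float = 25.0
    #: placeholder photon energy written to the SDEF card (user adapts it)
    photon_energy_mev: float = 0.662
    #: placeholder history count written to the NPS card
    nps: int = 1_000_000
    #: default seed of the sampling oracle
    sampling_seed: int = 20210828


_NESTED = {
    "holes": HoleConfig,
    "rod": RodConfig,
    "materials": MaterialConfig,
    "numbering": NumberingConfig,
}


def _coerce(value, template):
    """Coerce YAML lists to the tuple shapes used by the dataclasses."""
    if isinstance(template, tuple) and isinstance(value, (list, tuple)):
        return tuple(
            _coerce(v, template[0] if template else v) for v in value
        )
    return value


def _build(cls, data: dict, context: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(
            f"unknown configuration key(s) in {context}: "
            + ", ".join(sorted(unknown))
        )
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED and cls is PhantomConfig:
            if not isinstance(value, dict):
                raise ConfigError(f"configuration section '{key}' must be a mapping")
            kwargs[key] = _build(_NESTED[key], value, key)
        else:
            template = known[key].default
            if template is dataclasses.MISSING:
                template = None
            kwargs[key] = _coerce(value, template)
    return cls(**kwargs)


def validate_config(config: PhantomConfig) -> PhantomConfig:
    """Check physical ranges and cross-field consistency."""
    for name, dims in (("full_dims", config.full_dims), ("half_dims", config.half_dims)):
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ConfigError(f"{name} must be three positive lengths, got {dims!r}")
    h, r = config.holes, config.rod
    if len(h.source_offsets) != 4:
        raise ConfigError("exactly 4 source-hole offsets are required")
    if h.source_radius <= 0:
        raise ConfigError("source hole radius must be positive")
    if r.radius <= 0 or r.radius > h.source_radius:
        raise ConfigError(
            f"rod radius {r.radius} must be positive and not exceed the "
            f"hole radius {h.source_radius}"
        )
    if r.plug_length < 0:
        raise ConfigError("plug length must be non-negative")
    if h.connector_radius <= 0 or h.connector_depth <= 0:
        raise ConfigError("connector hole dimensions must be positive")
    m = config.materials
    if m.polyethylene_density <= 0 or m.air_density <= 0:
        raise ConfigError("material densities must be positive")
    if config.ldraw_scale <= 0:
        raise ConfigError("ldraw_scale must be positive")
    return config


def load_config(path: str | Path | None = None) -> PhantomConfig:
    """Load a configuration: full defaults if *path* is None, otherwise
    defaults merged with the YAML file at *path*.

    Unknown keys and out-of-range values raise :class:`ConfigError`.
    """
    if path is None:
        return validate_config(PhantomConfig())
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"configuration file {path} must contain a mapping")
    return validate_config(_build(PhantomConfig, data, "top level"))
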