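"""Domain model of the brick phantom and its segment lattice.

The Saint Petersburg brick phantom (UPh; also known as Igor, Olga or Irina)
is a stack of high-density-polyethylene bricks with drill holes for sealed
rod-shaped radionuclide sources.  Bricks come in two sizes, 16.5 x 11 x
5.5 cm (full) and 16.5 x 11 x 2.75 cm (half), i.e. side ratios 6:4:2 and
6:4:1.  The smallest occurring length, 2.75 cm, is the unit of the cubic
lattice on which bricks are placed and into which each brick is decomposed:
a full brick yields 6 x 4 x 2 = 48 cubic segments, a half brick 6 x 4 = 24.

Frame conventions (package choice, fixed here once):

* phantom frame: right-handed, z is the vertical stacking axis;
* brick-local axes: x spans 16.5 cm, y spans 11 cm, z spans the thickness,
  with the brick occupying ``[0, dims]`` and the source drill holes on the
  front face z = 0;
* lattice cells are half-open ``[i*u, (i+1)*u)`` per axis with 0-based
  (possibly negative) integer indices; a placement's ``index`` is the
  minimum-corner cell of its rotated footprint.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np

from .config import PhantomConfig
from .errors import CollisionError, ConfigError, GeometryError, OrientationError

LATTICE_TOL = 1e-9


class Vec3(NamedTuple):
    """A point or direction in cm (phantom or brick-local frame)."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


@dataclass(frozen=True)
class Orientation:
    """One of the 24 proper rotations of the cube, stored as a signed
    permutation matrix with determinant +1 (a physical brick cannot be
    mirrored, so improper matrices are rejected)."""

    rows: tuple[tuple[int, int, int], ...]

    def __post_init__(self):
        m = np.array(self.rows, dtype=int)
        if m.shape != (3, 3):
            raise OrientationError(f"orientation matrix must be 3x3, got {m.shape}")
        if not (
            np.all(np.abs(m).sum(axis=0) == 1)
            and np.all(np.abs(m).sum(axis=1) == 1)
            and np.isin(m, (-1, 0, 1)).all()
        ):
            raise OrientationError(
                f"matrix {self.rows} is not a signed permutation matrix"
            )
        if round(float(np.linalg.det(m))) != 1:
            raise OrientationError(
                f"matrix {self.rows} is a reflection (determinant != +1)"
            )

    @property
    def matrix(self) -> np.ndarray:
        return np.array(self.rows, dtype=int)

    @classmethod
    def identity(cls) -> "Orientation":
        return cls(((1, 0, 0), (0, 1, 0), (0, 0, 1)))

    @classmethod
    def from_matrix(cls, m, tol: float = 0.01) -> "Orientation":
        """Round a float matrix to the nearest signed permutation.

        Raises :class:`OrientationError` if any entry is farther than *tol*
        from its rounded value or the result is not a proper rotation.
        """
        m = np.asarray(m, dtype=float)
        r = np.rint(m).astype(int)
        if np.abs(m - r).max() > tol:
            raise OrientationError(
                f"matrix entries deviate from integers by more than {tol}: {m.tolist()}"
            )
        return cls(tuple(tuple(int(v) for v in row) for row in r))

    def apply(self, v) -> np.ndarray:
        return self.matrix @ np.asarray(v)

    def compose(self, other: "Orientation") -> "Orientation":
        """Rotation equal to applying *other* first, then *self*."""
        m = self.matrix @ other.matrix
        return Orientation(tuple(tuple(int(v) for v in row) for row in m))

    def inverse(self) -> "Orientation":
        m = self.matrix.T
        return Orientation(tuple(tuple(int(v) for v in row) for row in m))

    def is_identity(self) -> bool:
        return self.rows == ((1, 0, 0), (0, 1, 0), (0, 0, 1))

    def key(self) -> tuple:
        return self.rows


def all_orientations() -> list[Orientation]:
    """Enumerate the full proper rotation group of the cube (24 elements)."""
    out = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            m = np.zeros((3, 3), dtype=int)
            for r, (p, s) in enumerate(zip(perm, signs)):
                m[r, p] = s
            if round(float(np.linalg.det(m))) == 1:
                out.append(Orientation(tuple(tuple(int(v) for v in row) for row in m)))
    return out


def rot_z(quarter_turns: int) -> Orientation:
    """Rotation about the vertical axis by multiples of 90 degrees."""
    c, s = [(1, 0), (0, 1), (-1, 0), (0, -1)][quarter_turns % 4]
    return Orientation(((c, -s, 0), (s, c, 0), (0, 0, 1)))


def rot_x(quarter_turns: int) -> Orientation:
    c, s = [(1, 0), (0, 1), (-1, 0), (0, -1)][quarter_turns % 4]
    return Orientation(((1, 0, 0), (0, c, -s), (0, s, c)))


def rot_y(quarter_turns: int) -> Orientation:
    c, s = [(1, 0), (0, 1), (-1, 0), (0, -1)][quarter_turns % 4]
    return Orientation(((c, 0, s), (0, 1, 0), (-s, 0, c)))


@dataclass(frozen=True)
class HoleSpec:
    """A cylindrical drill hole in brick-local coordinates.

    ``kind`` is ``"source"`` (front-face rod-source hole) or ``"connector"``
    (blind hole for a metal connector on another face).  ``axis`` points
    from the face into the brick.
    """

    kind: str
    face: str
    center: Vec3
    axis: tuple[int, int, int]
    radius: float
    depth: float


@dataclass(frozen=True)
class RodSourceSpec:
    """Rod-source dimensions: active section flush with the front face,
    inactive plug behind it."""

    radius: float
    active_length: float
    plug_length: float


@dataclass(frozen=True)
class BrickTypeSpec:
    id: str
    dims: tuple[float, float, float]
    seg_counts: tuple[int, int, int]
    holes: tuple[HoleSpec, ...]
    rod: RodSourceSpec

    @property
    def volume(self) -> float:
        return self.dims[0] * self.dims[1] * self.dims[2]

    @property
    def n_segments(self) -> int:
        return self.seg_counts[0] * self.seg_counts[1] * self.seg_counts[2]

    @property
    def source_holes(self) -> tuple[HoleSpec, ...]:
        """The four rod-source drill holes, in hole-number order 1..4."""
        return tuple(h for h in self.holes if h.kind == "source")

    @property
    def connector_holes(self) -> tuple[HoleSpec, ...]:
        return tuple(h for h in self.holes if h.kind == "connector")

    def source_hole(self, number: int) -> HoleSpec:
        if not 1 <= number <= len(self.source_holes):
            raise GeometryError(
                f"source hole {number} out of range 1..{len(self.source_holes)}"
            )
        return self.source_holes[number - 1]


@dataclass(frozen=True)
class Placement:
    """A brick's pose on the lattice: minimum-corner cell index, one of the
    24 orientations, and at most one occupied source drill hole."""

    pid: str
    brick: str
    index: tuple[int, int, int]
    orientation: Orientation
    source_hole: int | None = None

    def __post_init__(self):
        if self.source_hole is not None and not 1 <= self.source_hole <= 4:
            raise GeometryError(
                f"placement {self.pid}: source hole must be 1..4, "
                f"got {self.source_hole}"
            )


@dataclass(frozen=True)
class Layout:
    placements: tuple[Placement, ...]

    def __post_init__(self):
        pids = [p.pid for p in self.placements]
        if len(set(pids)) != len(pids):
            dup = sorted({p for p in pids if pids.count(p) > 1})
            raise GeometryError(f"duplicate placement ids: {dup}")

    def __len__(self) -> int:
        return len(self.placements)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.placements:
            out[p.brick] = out.get(p.brick, 0) + 1
        return out

    def source_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.placements:
            if p.source_hole is not None:
                out[p.brick] = out.get(p.brick, 0) + 1
        return out


@dataclass(frozen=True)
class Segment:
    """One (2.75 cm)^3 piece of a placed brick.

    ``local`` is the segment's index within the (unrotated) brick template,
    ``cell`` the global lattice cell it occupies, ``universe`` the
    template-local segment ordinal (i-fastest linearisation; the MCNP
    writer maps it to a deck universe id) and ``transform`` the placement's
    rotation.
    """

    pid: str
    brick: str
    source_hole: int | None
    local: tuple[int, int, int]
    cell: tuple[int, int, int]
    universe: int
    transform: Orientation


@dataclass(frozen=True)
class SegmentMap:
    """Occupancy of the global lattice: each cell holds at most one segment."""

    origin: tuple[int, int, int]
    extents: tuple[int, int, int]
    occupancy: Mapping[tuple[int, int, int], Segment]

    @property
    def n_cells(self) -> int:
        return self.extents[0] * self.extents[1] * self.extents[2]


# ---------------------------------------------------------------------------
# registry construction

def make_brick_registry(
    config: PhantomConfig | None = None,
) -> dict[str, BrickTypeSpec]:
    """Build the full- and half-brick templates from a configuration.

    Validates that every brick dimension is an integer multiple of the
    lattice unit (the smallest dimension over all brick types) and that the
    hole and rod geometry fits inside the bricks.
    """
    cfg = config if config is not None else PhantomConfig()
    dims_by_type = {"full": tuple(cfg.full_dims), "half": tuple(cfg.half_dims)}
    unit = min(min(d) for d in dims_by_type.values())

    registry: dict[str, BrickTypeSpec] = {}
    for tid, dims in dims_by_type.items():
        seg_counts = []
        for d in dims:
            n = d / unit
            if abs(n - round(n)) > LATTICE_TOL:
                raise ConfigError(
                    f"{tid} brick dimension {d} cm is not an integer multiple "
                    f"of the lattice unit {unit} cm"
                )
            seg_counts.append(int(round(n)))
        dx, dy, dz = dims
        fcx, fcy = dx / 2.0, dy / 2.0
        depth = cfg.holes.source_depth if cfg.holes.source_depth is not None else dz
        if depth > dz + LATTICE_TOL:
            raise ConfigError(
                f"source hole depth {depth} exceeds {tid} brick thickness {dz}"
            )
        holes = []
        for ox, oy in cfg.holes.source_offsets:
            cx, cy = fcx + ox, fcy + oy
            if not (0 < cx < dx and 0 < cy < dy):
                raise ConfigError(
                    f"source hole offset ({ox}, {oy}) falls outside the "
                    f"{tid} brick front face"
                )
            holes.append(
                HoleSpec("source", "front", Vec3(cx, cy, 0.0), (0, 0, 1),
                         cfg.holes.source_radius, depth)
            )
        if cfg.holes.connector_depth > dy:
            raise ConfigError("connector hole depth exceeds the brick width")
        holes.append(
            HoleSpec("connector", "y_min", Vec3(dx / 2.0, 0.0, dz / 2.0),
                     (0, 1, 0), cfg.holes.connector_radius,
                     cfg.holes.connector_depth)
        )
        holes.append(
            HoleSpec("connector", "y_max", Vec3(dx / 2.0, dy, dz / 2.0),
                     (0, -1, 0), cfg.holes.connector_radius,
                     cfg.holes.connector_depth)
        )
        active = dz - cfg.rod.plug_length
        if active <= 0:
            raise ConfigError(
                f"rod plug length {cfg.rod.plug_length} leaves no active "
                f"section in the {tid} brick (thickness {dz})"
            )
        if active + cfg.rod.plug_length > depth + LATTICE_TOL:
            raise ConfigError("rod (active + plug) does not fit in the hole depth")
        if cfg.rod.radius > cfg.holes.source_radius:
            raise ConfigError("rod radius exceeds the hole radius")
        rod = RodSourceSpec(cfg.rod.radius, active, cfg.rod.plug_length)
        registry[tid] = BrickTypeSpec(tid, dims, tuple(seg_counts), tuple(holes), rod)
    return registry


def lattice_unit(registry: Mapping[str, BrickTypeSpec]) -> float:
    """The lattice spacing: the minimum edge length over all brick types
    (2.75 cm for the default registry)."""
    if not registry:
        raise ConfigError("empty brick registry")
    return min(min(spec.dims) for spec in registry.values())


# ---------------------------------------------------------------------------
# segmentation

def local_ordinal(local: tuple[int, int, int], seg_counts: tuple[int, int, int]) -> int:
    """i-fastest linearisation of a template-local segment index."""
    a, b, c = local
    sa, sb, _ = seg_counts
    return a + sa * (b + sb * c)


def footprint_delta(orientation: Orientation, seg_counts) -> np.ndarray:
    """Offset from a placement's rotation-anchor cell to its minimum-corner
    cell: per world axis, 0 if the mapped local axis keeps its sign, else
    minus that local axis' segment count."""
    m = orientation.matrix
    delta = np.zeros(3, dtype=int)
    for r in range(3):
        j = int(np.argmax(np.abs(m[r])))
        if m[r, j] < 0:
            delta[r] = -seg_counts[j]
    return delta


def segment_brick(
    placement: Placement, registry: Mapping[str, BrickTypeSpec]
) -> list[Segment]:
    """Decompose a placed brick into its unit-cube segments.

    Returns one :class:`Segment` per template cell; global cells are the
    placement index plus the orientation-rotated local offsets (exact
    integer arithmetic on doubled coordinates, so no rounding is involved).
    """
    spec = registry[placement.brick]
    m = placement.orientation.matrix
    sa, sb, sc = spec.seg_counts
    locals_ = [
        (a, b, c)
        for c in range(sc)
        for b in range(sb)
        for a in range(sa)
    ]
    # doubled local centre coordinates (2a+1, 2b+1, 2c+1) stay integral
    centers2 = np.array([(2 * a + 1, 2 * b + 1, 2 * c + 1) for a, b, c in locals_])
    rot2 = centers2 @ m.T
    lo2 = rot2.min(axis=0)
    offsets = (rot2 - lo2) // 2
    index = np.array(placement.index, dtype=int)
    segments = []
    for local, off in zip(locals_, offsets):
        cell = tuple(int(v) for v in (index + off))
        segments.append(
            Segment(
                pid=placement.pid,
                brick=placement.brick,
                source_hole=placement.source_hole,
                local=local,
                cell=cell,
                universe=local_ordinal(local, spec.seg_counts),
                transform=placement.orientation,
            )
        )
    return segments


def detect_collisions(
    layout: Layout, registry: Mapping[str, BrickTypeSpec]
) -> list[tuple[str, str, list[tuple[int, int, int]]]]:
    """Pairs of placements whose cell sets intersect, with the shared cells."""
    owner: dict[tuple[int, int, int], str] = {}
    shared: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for placement in layout.placements:
        for seg in segment_brick(placement, registry):
            prev = owner.get(seg.cell)
            if prev is None:
                owner[seg.cell] = placement.pid
            elif prev != placement.pid:
                shared.setdefault((prev, placement.pid), []).append(seg.cell)
    return [(a, b, sorted(cells)) for (a, b), cells in shared.items()]


def build_segment_map(
    layout: Layout, registry: Mapping[str, BrickTypeSpec]
) -> SegmentMap:
    """Rasterise a collision-free layout onto the global lattice.

    Raises :class:`CollisionError` naming the conflicting placements and
    cells if two bricks overlap.
    """
    occupancy: dict[tuple[int, int, int], Segment] = {}
    for placement in layout.placements:
        for seg in segment_brick(placement, registry):
            prev = occupancy.get(seg.cell)
            if prev is not None:
                conflicts = detect_collisions(layout, registry)
                pairs = ", ".join(
                    f"{a}/{b} ({len(cells)} cells)" for a, b, cells in conflicts
                )
                raise CollisionError(
                    f"overlapping placements: {pairs}", conflicts=conflicts
                )
            occupancy[seg.cell] = seg
    if not occupancy:
        return SegmentMap(origin=(0, 0, 0), extents=(0, 0, 0), occupancy={})
    cells = np.array(list(occupancy), dtype=int)
    lo = cells.min(axis=0)
    hi = cells.max(axis=0)
    return SegmentMap(
        origin=tuple(int(v) for v in lo),
        extents=tuple(int(v) for v in (hi - lo + 1)),
        occupancy=occupancy,
    )


def layout_mass(
    layout: Layout, registry: Mapping[str, BrickTypeSpec], density: float
) -> float:
    """Total brick mass in kg at *density* g/cm^3, holes ignored
    (solid-brick approximation)."""
    if density <= 0:
        raise ConfigError(f"density must be positive, got {density}")
    volume = sum(registry[p.brick].volume for p in layout.placements)
    return density * volume / 1000.0


def brick_local_frame(
    placement: Placement, registry: Mapping[str, BrickTypeSpec]
) -> tuple[np.ndarray, np.ndarray]:
    """World pose of a placed brick as ``world = M @ local + T``.

    ``T`` is fixed by the convention that the rotated brick's bounding-box
    minimum corner sits at ``index * u``.
    """
    spec = registry[placement.brick]
    u = lattice_unit(registry)
    m = placement.orientation.matrix
    dims = np.array(spec.dims, dtype=float)
    mins = np.minimum(m @ dims, 0.0)  # per-axis min over the 8 rotated corners
    t = np.array(placement.index, dtype=float) * u - mins
    return m, t
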