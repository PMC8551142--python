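"""Build the MCNP SDEF source definition for the rod sources.

Each occupied source drill hole holds one rod source whose active section
starts flush with the brick's front face.  Sampling follows two rules:

* per-source weighting: every full-brick source carries equal probability
  and every half-brick source half of it (implemented as weight
  proportional to brick thickness, which reduces to 1 : 1/2 for the
  default registry);
* within a source, the spatial distribution is uniform, so the probability
  share of each traversed (2.75 cm)^3 lattice segment is the active length
  contained in that segment divided by the total active length.

The emitted cards use the classic cell-rejection pattern: a discrete cell
distribution (SI L of lattice-path cell references with SP probabilities)
plus dependent per-entry position distributions that sample uniformly over
the segment-clipped bounding box of the cylinder, rejected against the
source cell.  Bounding boxes are clipped per segment so each entry samples
only its own cell and the rejection efficiency stays >= pi/4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .brick_model import (
    BrickTypeSpec,
    Layout,
    SegmentMap,
    Vec3,
    brick_local_frame,
    build_segment_map,
    lattice_unit,
)
from .errors import GeometryError

PROB_TOL = 1e-12


@dataclass(frozen=True)
class SourceRecord:
    """A rod source in world coordinates."""

    pid: str
    brick: str
    hole: int
    base: Vec3                    # active-section start (front face), cm
    axis: tuple[int, int, int]    # world unit vector along the hole
    radius: float
    active_length: float
    weight: float                 # unnormalised per-source weight

    def point_at(self, t: float) -> np.ndarray:
        return self.base.as_array() + t * np.array(self.axis, dtype=float)


@dataclass(frozen=True)
class SourceEntry:
    """One (source, lattice segment) sampling entry."""

    pid: str
    hole: int
    cell: tuple[int, int, int]    # global lattice cell
    source_cell: int | None       # MCNP core-cell id (None without a plan)
    fill_cell: int | None         # segment-universe fill cell on the path
    bbox: tuple[Vec3, Vec3]       # world-frame axis-aligned sampling box
    t0: float                     # active-length interval inside the cell
    t1: float
    probability: float


@dataclass(frozen=True)
class SourceDistribution:
    entries: tuple[SourceEntry, ...]

    def __post_init__(self):
        if self.entries:
            total = sum(e.probability for e in self.entries)
            if abs(total - 1.0) > 1e-9:
                raise GeometryError(
                    f"source probabilities sum to {total!r}, not 1"
                )
            if any(e.probability <= 0 for e in self.entries):
                raise GeometryError("source probabilities must be positive")

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([e.probability for e in self.entries], dtype=float)


def collect_sources(
    layout: Layout, registry: Mapping[str, BrickTypeSpec]
) -> list[SourceRecord]:
    """One record per placement with an occupied source hole, with the
    hole's local geometry mapped through the placement pose."""
    max_thickness = max(spec.dims[2] for spec in registry.values())
    records = []
    for p in layout.placements:
        if p.source_hole is None:
            continue
        spec = registry[p.brick]
        hole = spec.source_hole(p.source_hole)
        m, t = brick_local_frame(p, registry)
        base = m @ hole.center.as_array() + t
        axis = m @ np.array(hole.axis, dtype=int)
        records.append(
            SourceRecord(
                pid=p.pid,
                brick=p.brick,
                hole=p.source_hole,
                base=Vec3(*(float(v) for v in base)),
                axis=tuple(int(v) for v in axis),
                radius=spec.rod.radius,
                active_length=spec.rod.active_length,
                weight=spec.dims[2] / max_thickness,
            )
        )
    return records


def source_weights(
    records: Sequence[SourceRecord],
    registry: Mapping[str, BrickTypeSpec] | None = None,
) -> np.ndarray:
    """Normalised per-source probabilities (full : half = 1 : 1/2)."""
    if not records:
        raise GeometryError("no sources defined")
    raw = np.array([r.weight for r in records], dtype=float)
    return raw / raw.sum()


def segment_fractions(
    record: SourceRecord,
    segment_map: SegmentMap,
    registry: Mapping[str, BrickTypeSpec],
) -> list[tuple[tuple[int, int, int], float, float, float]]:
    """Split a rod's active length over the lattice cells it traverses.

    Returns ``(cell, t0, t1, share)`` tuples ordered front-to-back, where
    ``[t0, t1]`` is the active-length interval inside the cell and
    ``share = (t1 - t0) / active_length``.  Every traversed cell must be
    occupied by the record's own placement, else the cylinder would leave
    its brick and a :class:`GeometryError` is raised.
    """
    u = lattice_unit(registry)
    base = record.base.as_array()
    axis = np.array(record.axis, dtype=float)
    ax = int(np.argmax(np.abs(axis)))
    sign = float(axis[ax])
    w0 = base[ax]
    w1 = w0 + sign * record.active_length
    lo, hi = min(w0, w1), max(w0, w1)
    out = []
    for k in range(math.floor(lo / u + PROB_TOL), math.ceil(hi / u - PROB_TOL)):
        seg_lo = max(lo, k * u)
        seg_hi = min(hi, (k + 1) * u)
        if seg_hi - seg_lo <= PROB_TOL:
            continue
        cell = [int(math.floor((base[j] / u) + 1e-9)) for j in range(3)]
        cell[ax] = k
        cell = tuple(cell)
        occupant = segment_map.occupancy.get(cell)
        if occupant is None or occupant.pid != record.pid:
            raise GeometryError(
                f"source {record.pid} hole {record.hole}: active section "
                f"reaches lattice cell {cell} outside its brick"
            )
        # convert the world-axis interval back to rod parameter t
        if sign > 0:
            t0, t1 = seg_lo - w0, seg_hi - w0
        else:
            t0, t1 = w0 - seg_hi, w0 - seg_lo
        out.append((cell, t0, t1, (seg_hi - seg_lo) / record.active_length))
    out.sort(key=lambda item: item[1])
    return out


def _entry_bbox(record: SourceRecord, t0: float, t1: float) -> tuple[Vec3, Vec3]:
    p0 = record.point_at(t0)
    p1 = record.point_at(t1)
    lateral = (1 - np.abs(np.array(record.axis))) * record.radius
    lo = np.minimum(p0, p1) - lateral
    hi = np.maximum(p0, p1) + lateral
    return Vec3(*(float(v) for v in lo)), Vec3(*(float(v) for v in hi))


def build_source_distribution(
    layout: Layout,
    registry: Mapping[str, BrickTypeSpec],
    segment_map: SegmentMap | None = None,
    plan=None,
) -> tuple[list[SourceRecord], SourceDistribution]:
    """Full pipeline: records, weights, per-segment split, entry list.

    Entries are ordered by placement id, then by position along the rod;
    with a :class:`~brickphantom.mcnp_writer.NumberingPlan` each entry also
    carries the MCNP cell ids used on the SI L path.
    """
    if segment_map is None:
        segment_map = build_segment_map(layout, registry)
    records = sorted(collect_sources(layout, registry), key=lambda r: r.pid)
    if not records:
        return [], SourceDistribution(entries=())
    weights = source_weights(records, registry)
    entries = []
    for record, weight in zip(records, weights):
        for cell, t0, t1, share in segment_fractions(record, segment_map, registry):
            seg = segment_map.occupancy[cell]
            source_cell = fill_cell = None
            if plan is not None:
                variant = plan.variant_index(seg.brick, seg.source_hole)
                source_cell = plan.core_cell(variant, record.hole)
                fill_cell = plan.segment_fill_cell(variant, seg.universe)
            entries.append(
                SourceEntry(
                    pid=record.pid,
                    hole=record.hole,
                    cell=cell,
                    source_cell=source_cell,
                    fill_cell=fill_cell,
                    bbox=_entry_bbox(record, t0, t1),
                    t0=t0,
                    t1=t1,
                    probability=float(weight * share),
                )
            )
    return records, SourceDistribution(entries=tuple(entries))


def _fmt(value: float) -> str:
    if value == int(value) and abs(value) < 1e15:
        return str(int(value))
    return f"{value:.12g}"


def emit_sdef(
    records: Sequence[SourceRecord],
    distribution: SourceDistribution,
    plan,
    config,
) -> list[str]:
    """Serialise the source definition to MCNP data cards.

    Distribution 1 is the discrete cell distribution; distributions 2-4
    select, per sampled cell, the dependent uniform x/y/z distributions
    (numbers 5 + 3k, 6 + 3k, 7 + 3k for entry k).
    """
    if not distribution.entries:
        return ["c no rod sources defined; add an sdef card before running"]
    entries = distribution.entries
    cards = [
        f"sdef par=2 cel=d1 x=fcel=d2 y=fcel=d3 z=fcel=d4 "
        f"erg={_fmt(config.photon_energy_mev)} $ energy: adapt to the nuclide"
    ]
    paths = []
    for e in entries:
        i, j, k = e.cell
        paths.append(
            f"({e.source_cell} < {e.fill_cell} < "
            f"{plan.lattice_cell}[{i} {j} {k}] < {plan.world_cell})"
        )
    cards.append("si1 l " + " ".join(paths))
    cards.append("sp1 " + " ".join(_fmt(e.probability) for e in entries))
    base = 5
    for axis_i, letter in enumerate("234"):
        nums = " ".join(str(base + 3 * k + axis_i) for k in range(len(entries)))
        cards.append(f"ds{letter} s {nums}")
    for k, e in enumerate(entries):
        lo, hi = e.bbox
        for axis_i in range(3):
            d = base + 3 * k + axis_i
            cards.append(f"si{d} h {_fmt(lo[axis_i])} {_fmt(hi[axis_i])}")
            cards.append(f"sp{d} 0 1")
    return cards
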