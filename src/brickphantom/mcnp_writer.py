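"""Serialise a brick layout into a complete MCNP6 input deck.

Deck structure (MCNP6.2-compatible):

* title card + cell block / blank line / surface block / blank line / data
  block;
* each placed-brick *variant* (brick type x occupied source hole) gets one
  brick universe built from rpp/rcc macro-bodies — polyethylene body,
  the four source drill holes (rod core + annular gap each), the connector
  blind holes, and the surrounding air — plus 48 (full) or 24 (half)
  segment universes, each clipping the brick to one (2.75 cm)^3 cube via a
  translated universe/fill;
* one LAT=1 lattice cell with a fully specified FILL array (i-fastest
  entry order) whose entries reference segment universes, with at most 24
  shared TR cards for the distinct non-identity orientations (identity is
  emitted without a transform) and a background air universe for empty
  cells;
* data block with materials (high-density polyethylene as CH2 at
  0.95 g/cm^3, air), TR cards, MODE P, the SDEF block from
  :mod:`~brickphantom.source_builder`, and an NPS placeholder.  Photon
  energy and history count are placeholders the user adapts.

Every card is wrapped to 78 characters with 5-blank continuations, and the
finished deck is checked by an internal reference-closure linter before it
is returned, so :func:`emit_deck` is a pure, validated function of
(layout, registry, config) and byte-identical for identical inputs.

Geometric conventions that the cards encode:

* lattice element [0,0,0] is the cube centred on the lattice-universe
  origin, so per-element fill transforms rotate about the element centre;
* the container cell places the lattice universe shifted by half a unit,
  which maps world cell ``[i*u, (i+1)*u)`` onto element ``[i,j,k]``;
* TR cards carry zero displacement and the placement rotation matrix
  row-major (main-frame coordinates = matrix times universe coordinates).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .brick_model import (
    BrickTypeSpec,
    Layout,
    Orientation,
    SegmentMap,
    all_orientations,
    build_segment_map,
    lattice_unit,
    local_ordinal,
)
from .config import PhantomConfig
from .errors import DeckError
from . import source_builder

LINE_LIMIT = 78
CONTINUATION = "     "  # 5 blanks

Variant = tuple[str, int | None]


def _fmt(value: float) -> str:
    if value == int(value) and abs(value) < 1e15:
        return str(int(value))
    return f"{value:.12g}"


@dataclass(frozen=True)
class McnpDeck:
    """Structured card sets; :meth:`serialize` renders the three
    blank-line-delimited blocks."""

    title: str
    cell_cards: tuple[str, ...]
    surface_cards: tuple[str, ...]
    data_cards: tuple[str, ...]

    def serialize(self) -> str:
        lines: list[str] = [self.title]
        for card in self.cell_cards:
            lines.extend(wrap_card(card))
        lines.append("")
        for card in self.surface_cards:
            lines.extend(wrap_card(card))
        lines.append("")
        for card in self.data_cards:
            lines.extend(wrap_card(card))
        return "\n".join(lines) + "\n"


class NumberingPlan:
    """Deterministic id assignment for surfaces, cells, universes,
    transforms and materials, given the set of brick variants and
    orientations a layout uses."""

    def __init__(
        self,
        config: PhantomConfig,
        registry: Mapping[str, BrickTypeSpec],
        variants: Sequence[Variant],
        orientations: Sequence[Orientation] = (),
    ):
        self.cfg = config.numbering
        self.registry = registry
        self.variants = list(variants)
        self._variant_index = {v: i for i, v in enumerate(self.variants)}
        self.type_order = list(registry)
        self._type_index = {t: i for i, t in enumerate(self.type_order)}
        self.plug = registry[self.type_order[0]].rod.plug_length > 0
        distinct = sorted(
            {o.key() for o in orientations if not o.is_identity()}
        )
        self.tr_numbers = {
            key: self.cfg.tr_base + i for i, key in enumerate(distinct)
        }

    # -- identity helpers ---------------------------------------------------
    @property
    def world_cell(self) -> int:
        return self.cfg.world_cell

    @property
    def lattice_cell(self) -> int:
        return self.cfg.lattice_cell

    def variant_index(self, brick: str, source_hole: int | None) -> int:
        return self._variant_index[(brick, source_hole)]

    def brick_universe(self, variant: int) -> int:
        return self.cfg.brick_universe_base + variant

    def template_cell(self, variant: int, slot: int) -> int:
        return self.cfg.template_cell_base + self.cfg.template_cell_stride * variant + slot

    def core_cell(self, variant: int, hole: int) -> int:
        """The rod-core cell of source hole *hole* in a brick universe."""
        slot = 3 * hole - 1 if self.plug else 2 * hole
        return self.template_cell(variant, slot)

    def gap_cell(self, variant: int, hole: int) -> int:
        slot = 3 * hole - 2 if self.plug else 2 * hole - 1
        return self.template_cell(variant, slot)

    def plug_cell(self, variant: int, hole: int) -> int:
        if not self.plug:
            raise DeckError("no plug cells: plug length is zero")
        return self.template_cell(variant, 3 * hole)

    def _after_holes(self) -> int:
        return 13 if self.plug else 9

    def connector_cell(self, variant: int, conn: int) -> int:
        return self.template_cell(variant, self._after_holes() + conn)

    def outside_cell(self, variant: int) -> int:
        n_conn = len(self.registry[self.variants[variant][0]].connector_holes)
        return self.template_cell(variant, self._after_holes() + n_conn)

    def surface(self, brick: str, slot: int) -> int:
        return self.cfg.surface_base + self.cfg.surface_stride * self._type_index[brick] + slot

    def segment_universe(self, variant: int, ordinal: int) -> int:
        return self.cfg.segment_universe_base + self.cfg.segment_universe_stride * variant + ordinal

    def segment_fill_cell(self, variant: int, ordinal: int) -> int:
        return self.cfg.segment_cell_base + self.cfg.segment_cell_stride * variant + 2 * ordinal

    def segment_air_cell(self, variant: int, ordinal: int) -> int:
        return self.segment_fill_cell(variant, ordinal) + 1

    def tr_number(self, orientation: Orientation) -> int | None:
        if orientation.is_identity():
            return None
        return self.tr_numbers[orientation.key()]


def used_variants(layout: Layout, registry: Mapping[str, BrickTypeSpec]) -> list[Variant]:
    """Brick variants present in a layout, in deterministic order
    (registry type order, then source hole none, 1..4)."""
    present = {(p.brick, p.source_hole) for p in layout.placements}
    order = []
    for brick in registry:
        for hole in (None, 1, 2, 3, 4):
            if (brick, hole) in present:
                order.append((brick, hole))
    return order


def make_plan(
    layout: Layout,
    registry: Mapping[str, BrickTypeSpec],
    config: PhantomConfig,
) -> NumberingPlan:
    return NumberingPlan(
        config,
        registry,
        used_variants(layout, registry),
        [p.orientation for p in layout.placements],
    )


# ---------------------------------------------------------------------------
# card emission

def _air(config: PhantomConfig) -> str:
    return f"{config.numbering.material_air} -{_fmt(config.materials.air_density)}"


def emit_template_universes(
    registry: Mapping[str, BrickTypeSpec],
    config: PhantomConfig,
    plan: NumberingPlan,
    variants: Sequence[Variant] | None = None,
) -> tuple[list[str], list[str]]:
    """Brick-variant universes and their segment universes.

    Returns (cell cards, surface cards).  Surfaces depend only on the brick
    type (hole geometry is identical with or without a rod), so they are
    emitted once per type; cells are emitted per variant, with the rod-core
    cells air-filled when the hole holds no source so the cell count does
    not depend on the source assignment.
    """
    if variants is None:
        variants = plan.variants
    num = config.numbering
    poly = f"{num.material_polyethylene} -{_fmt(config.materials.polyethylene_density)}"
    air = _air(config)
    surface_cards: list[str] = []
    cell_cards: list[str] = []

    types_used = []
    for brick, _ in variants:
        if brick not in types_used:
            types_used.append(brick)

    for brick in types_used:
        spec = registry[brick]
        dx, dy, dz = spec.dims
        s0 = plan.surface(brick, 0)
        surface_cards.append(
            f"{s0} rpp 0 {_fmt(dx)} 0 {_fmt(dy)} 0 {_fmt(dz)} "
            f"$ {brick} brick body"
        )
        for j, hole in enumerate(spec.source_holes, start=1):
            a = np.array(hole.axis) * hole.depth
            c = hole.center
            surface_cards.append(
                f"{plan.surface(brick, j)} rcc {_fmt(c.x)} {_fmt(c.y)} {_fmt(c.z)} "
                f"{_fmt(a[0])} {_fmt(a[1])} {_fmt(a[2])} {_fmt(hole.radius)} "
                f"$ {brick} source hole {j}"
            )
            rod_len = spec.rod.active_length + spec.rod.plug_length
            a_rod = np.array(hole.axis) * rod_len
            surface_cards.append(
                f"{plan.surface(brick, 4 + j)} rcc {_fmt(c.x)} {_fmt(c.y)} {_fmt(c.z)} "
                f"{_fmt(a_rod[0])} {_fmt(a_rod[1])} {_fmt(a_rod[2])} "
                f"{_fmt(spec.rod.radius)} $ {brick} rod core {j}"
            )
        if plan.plug:
            surface_cards.append(
                f"{plan.surface(brick, 9)} pz {_fmt(spec.rod.active_length)} "
                f"$ {brick} active/plug boundary"
            )
        for ci, hole in enumerate(spec.connector_holes):
            a = np.array(hole.axis) * hole.depth
            c = hole.center
            surface_cards.append(
                f"{plan.surface(brick, 10 + ci)} rcc {_fmt(c.x)} {_fmt(c.y)} {_fmt(c.z)} "
                f"{_fmt(a[0])} {_fmt(a[1])} {_fmt(a[2])} {_fmt(hole.radius)} "
                f"$ {brick} connector hole"
            )

    for variant_i, (brick, source_hole) in enumerate(variants):
        spec = registry[brick]
        u_brick = plan.brick_universe(variant_i)
        s0 = plan.surface(brick, 0)
        hole_surfs = [plan.surface(brick, j) for j in range(1, 5)]
        conn_surfs = [
            plan.surface(brick, 10 + ci)
            for ci in range(len(spec.connector_holes))
        ]
        tag = f"{brick}" + (f" source in hole {source_hole}" if source_hole else "")
        body_geom = f"-{s0} " + " ".join(
            str(s) for s in hole_surfs + conn_surfs
        )
        cell_cards.append(
            f"{plan.template_cell(variant_i, 0)} {poly} {body_geom} "
            f"u={u_brick} imp:p=1 $ {tag} body"
        )
        for j in range(1, 5):
            sh = plan.surface(brick, j)
            sc = plan.surface(brick, 4 + j)
            cell_cards.append(
                f"{plan.gap_cell(variant_i, j)} {air} -{sh} {sc} "
                f"u={u_brick} imp:p=1 $ hole {j} annular gap"
            )
            occupied = source_hole == j
            label = "rod" if occupied else "empty hole core"
            if plan.plug:
                sp = plan.surface(brick, 9)
                cell_cards.append(
                    f"{plan.core_cell(variant_i, j)} {air} -{sc} -{sp} "
                    f"u={u_brick} imp:p=1 $ {label} active section"
                )
                cell_cards.append(
                    f"{plan.plug_cell(variant_i, j)} {air} -{sc} {sp} "
                    f"u={u_brick} imp:p=1 $ {label} plug"
                )
            else:
                cell_cards.append(
                    f"{plan.core_cell(variant_i, j)} {air} -{sc} "
                    f"u={u_brick} imp:p=1 $ {label}"
                )
        for ci in range(len(spec.connector_holes)):
            cell_cards.append(
                f"{plan.connector_cell(variant_i, ci)} {air} "
                f"-{plan.surface(brick, 10 + ci)} u={u_brick} imp:p=1 "
                f"$ connector hole void"
            )
        cell_cards.append(
            f"{plan.outside_cell(variant_i)} {air} {s0} u={u_brick} imp:p=1 "
            f"$ air around {brick} brick"
        )

        # segment universes: one unit cube each, filled with the brick
        # universe translated so segment (a, b, c) is centred on the origin
        unit = lattice_unit(registry)
        elem = config.numbering.element_surface
        sa, sb, sc_ = spec.seg_counts
        for c in range(sc_):
            for b in range(sb):
                for a in range(sa):
                    ordinal = local_ordinal((a, b, c), spec.seg_counts)
                    u_seg = plan.segment_universe(variant_i, ordinal)
                    shift = [-(i + 0.5) * unit for i in (a, b, c)]
                    cell_cards.append(
                        f"{plan.segment_fill_cell(variant_i, ordinal)} 0 -{elem} "
                        f"u={u_seg} imp:p=1 fill={u_brick} "
                        f"({_fmt(shift[0])} {_fmt(shift[1])} {_fmt(shift[2])})"
                    )
                    cell_cards.append(
                        f"{plan.segment_air_cell(variant_i, ordinal)} {air} {elem} "
                        f"u={u_seg} imp:p=1"
                    )
    return cell_cards, surface_cards


def emit_lattice(
    segment_map: SegmentMap, plan: NumberingPlan, config: PhantomConfig
) -> tuple[list[str], list[str]]:
    """The LAT=1 lattice cell with its fully specified FILL array, the
    background-universe cells and the shared TR cards.

    FILL entries run i-fastest, then j, then k; empty cells reference the
    background air universe; rotated segments append their ``(tr)``
    reference.  Raises :class:`DeckError` on an empty map.
    """
    if segment_map.n_cells == 0:
        raise DeckError("cannot emit a lattice for an empty layout")
    num = config.numbering
    o = segment_map.origin
    n = segment_map.extents
    ranges = " ".join(f"{o[d]}:{o[d] + n[d] - 1}" for d in range(3))
    entries = []
    for k in range(o[2], o[2] + n[2]):
        for j in range(o[1], o[1] + n[1]):
            for i in range(o[0], o[0] + n[0]):
                seg = segment_map.occupancy.get((i, j, k))
                if seg is None:
                    entries.append(str(num.background_universe))
                    continue
                variant = plan.variant_index(seg.brick, seg.source_hole)
                universe = plan.segment_universe(variant, seg.universe)
                tr = plan.tr_number(seg.transform)
                entries.append(f"{universe}" if tr is None else f"{universe} ({tr})")
    air = _air_from_num(num, config)
    cells = [
        f"{num.lattice_cell} 0 -{num.element_surface} lat=1 "
        f"u={num.lattice_universe} imp:p=1 fill={ranges} " + " ".join(entries),
        f"{num.background_cells[0]} {air} -{num.element_surface} "
        f"u={num.background_universe} imp:p=1 $ background air",
        f"{num.background_cells[1]} {air} {num.element_surface} "
        f"u={num.background_universe} imp:p=1 $ background air",
    ]
    tr_cards = [
        f"tr{trn} 0 0 0 " + " ".join(
            str(v) for row in key for v in row
        ) + " $ segment rotation"
        for key, trn in sorted(plan.tr_numbers.items(), key=lambda kv: kv[1])
    ]
    return cells, tr_cards


def _air_from_num(num, config: PhantomConfig) -> str:
    return f"{num.material_air} -{_fmt(config.materials.air_density)}"


def _world_cards(
    segment_map: SegmentMap, plan: NumberingPlan, config: PhantomConfig,
    unit: float,
) -> tuple[list[str], list[str]]:
    num = config.numbering
    o = np.array(segment_map.origin, dtype=float) * unit
    hi = o + np.array(segment_map.extents, dtype=float) * unit
    pad = 50.0
    surfaces = [
        f"{num.world_surface} rpp "
        + " ".join(f"{_fmt(o[d] - pad)} {_fmt(hi[d] + pad)}" for d in range(3))
        + " $ world boundary",
        f"{num.container_surface} rpp "
        + " ".join(f"{_fmt(o[d])} {_fmt(hi[d])}" for d in range(3))
        + " $ lattice container",
        f"{num.element_surface} rpp "
        + " ".join(f"{_fmt(-unit / 2)} {_fmt(unit / 2)}" for _ in range(3))
        + " $ lattice element",
    ]
    half = unit / 2.0
    cells = [
        f"{num.world_cell} 0 -{num.container_surface} imp:p=1 "
        f"fill={num.lattice_universe} ({_fmt(half)} {_fmt(half)} {_fmt(half)})",
        f"{num.outside_cell} {_air_from_num(num, config)} -{num.world_surface} "
        f"{num.container_surface} imp:p=1 $ room air",
        f"{num.graveyard_cell} 0 {num.world_surface} imp:p=0 $ graveyard",
    ]
    return cells, surfaces


def _material_cards(config: PhantomConfig) -> list[str]:
    num = config.numbering
    return [
        f"m{num.material_polyethylene} 1001 2 6000 1 "
        f"$ high-density polyethylene (CH2)",
        f"m{num.material_air} 7014 -0.755 8016 -0.232 18000 -0.013 $ air",
    ]


def emit_deck(
    layout: Layout,
    registry: Mapping[str, BrickTypeSpec],
    config: PhantomConfig | None = None,
) -> str:
    """Serialise a collision-free layout to a complete MCNP input deck.

    Pure function of its inputs: identical inputs give byte-identical
    output.  The deck is validated by :func:`lint_deck` before it is
    returned.
    """
    cfg = config if config is not None else PhantomConfig()
    segment_map = build_segment_map(layout, registry)
    plan = make_plan(layout, registry, cfg)
    unit = lattice_unit(registry)

    counts = layout.counts()
    title = (
        "Brick phantom: "
        + " + ".join(f"{counts.get(t, 0)} {t}" for t in registry)
        + " bricks (auto-generated deck)"
    )

    template_cells, template_surfaces = emit_template_universes(
        registry, cfg, plan
    )
    lattice_cells, tr_cards = emit_lattice(segment_map, plan, cfg)
    world_cells, world_surfaces = _world_cards(segment_map, plan, cfg, unit)

    records, distribution = source_builder.build_source_distribution(
        layout, registry, segment_map=segment_map, plan=plan
    )
    sdef_cards = source_builder.emit_sdef(records, distribution, plan, cfg)

    data_cards = (
        ["mode p"]
        + _material_cards(cfg)
        + tr_cards
        + sdef_cards
        + [f"nps {cfg.nps} $ history count: adapt as needed"]
    )
    deck = McnpDeck(
        title=title,
        cell_cards=tuple(world_cells + lattice_cells + template_cells),
        surface_cards=tuple(world_surfaces + template_surfaces),
        data_cards=tuple(data_cards),
    )
    text = deck.serialize()
    issues = lint_deck(text)
    if issues:
        raise DeckError("generated deck failed internal lint:\n" + "\n".join(issues))
    return text


# ---------------------------------------------------------------------------
# wrapping and linting

_TOKEN_RE = re.compile(r"\([^()]*\)|\S+")


def tokenize_card(text: str) -> list[str]:
    """Split a card into whitespace-delimited tokens, keeping
    parenthesised groups (transforms, cell paths) intact."""
    return _TOKEN_RE.findall(text)


def wrap_card(text: str, limit: int = LINE_LIMIT) -> list[str]:
    """Wrap a logical card onto physical lines of at most *limit*
    characters; continuation lines start with five blanks.  Token
    boundaries are preserved, so re-joining the tokens reproduces the
    card.  A single token longer than the limit is an error."""
    tokens = tokenize_card(text)
    if not tokens:
        return [""]
    lines: list[str] = []
    current = ""
    for token in tokens:
        width = limit - (len(CONTINUATION) if lines else 0)
        if len(token) > limit - len(CONTINUATION):
            raise DeckError(
                f"token {token[:40]!r}... exceeds the {limit}-character line limit"
            )
        candidate = token if not current else f"{current} {token}"
        if len(candidate) <= (limit if not lines else limit - len(CONTINUATION)):
            current = candidate
        else:
            lines.append(current)
            current = token
    lines.append(current)
    return [lines[0]] + [CONTINUATION + line for line in lines[1:]]


def unwrap_cards(block_lines: Sequence[str]) -> list[str]:
    """Inverse of per-card wrapping over a block: join continuation lines
    (those starting with five blanks) onto their card."""
    cards: list[str] = []
    for line in block_lines:
        if line.startswith(CONTINUATION) and cards:
            cards[-1] += " " + line.strip()
        elif line.strip().lower().startswith("c ") or line.strip() == "c":
            continue
        elif line.strip():
            cards.append(line.strip())
    return cards


def _strip_comment(card: str) -> str:
    return card.split("$", 1)[0].strip()


_INT_RE = re.compile(r"-?\d+")


def lint_deck(text: str) -> list[str]:
    """Structural linter: three blocks; every referenced surface, cell,
    universe, transform and material id is defined; FILL array length
    matches its index ranges.  Returns a list of human-readable issues
    (empty when the deck is clean)."""
    issues: list[str] = []
    blocks = text.split("\n\n")
    if len(blocks) != 3:
        return [f"expected 3 blank-line-delimited blocks, found {len(blocks)}"]
    cell_lines = blocks[0].splitlines()[1:]  # drop the title card
    cell_cards = unwrap_cards(cell_lines)
    surface_cards = unwrap_cards(blocks[1].splitlines())
    data_cards = unwrap_cards(blocks[2].splitlines())

    defined_surfaces = set()
    for card in surface_cards:
        tokens = _strip_comment(card).split()
        if tokens:
            defined_surfaces.add(int(tokens[0]))

    defined_cells, defined_universes, defined_materials_used = set(), set(), set()
    used_surfaces, used_universes, used_trs, used_cells = set(), set(), set(), set()
    fill_checks: list[tuple[int, int, int]] = []

    for card in cell_cards:
        body = _strip_comment(card)
        tokens = tokenize_card(body)
        if not tokens:
            continue
        try:
            cell_id = int(tokens[0])
            material = int(tokens[1])
        except ValueError:
            issues.append(f"unparseable cell card: {card[:60]}")
            continue
        defined_cells.add(cell_id)
        pos = 2
        if material != 0:
            defined_materials_used.add(material)
            pos += 1  # density
        in_fill = False
        fill_ranges: list[tuple[int, int]] = []
        fill_entries = 0
        while pos < len(tokens):
            token = tokens[pos]
            low = token.lower()
            if "=" in low and not low.startswith("("):
                in_fill = False
                key, _, value = low.partition("=")
                if key == "u":
                    defined_universes.add(int(value))
                elif key == "fill":
                    if ":" in value:
                        in_fill = True
                        a, _, b = value.partition(":")
                        fill_ranges.append((int(a), int(b)))
                    else:
                        used_universes.add(int(value))
                elif key in ("lat", "imp:p"):
                    pass
            elif in_fill and ":" in low:
                a, _, b = low.partition(":")
                fill_ranges.append((int(a), int(b)))
            elif low.startswith("("):
                inner = low.strip("()").split()
                if len(inner) == 1:
                    used_trs.add(int(inner[0]))
                # 3 numbers: a fill translation; nothing to resolve
            elif in_fill:
                used_universes.add(int(low))
                fill_entries += 1
            else:
                used_surfaces.add(abs(int(low)))
            pos += 1
        if fill_ranges:
            expected = 1
            for a, b in fill_ranges:
                expected *= b - a + 1
            if len(fill_ranges) != 3:
                issues.append(f"cell {cell_id}: fill needs 3 index ranges")
            elif fill_entries != expected:
                issues.append(
                    f"cell {cell_id}: fill array has {fill_entries} entries, "
                    f"expected {expected}"
                )

    defined_trs, defined_materials = set(), set()
    for card in data_cards:
        body = _strip_comment(card)
        if not body:
            continue
        head = body.split()[0].lower()
        if head.startswith("tr") and head[2:].isdigit():
            defined_trs.add(int(head[2:]))
        elif head.startswith("m") and head[1:].isdigit():
            defined_materials.add(int(head[1:]))
        elif head.startswith("si") and " l " in body.lower():
            for path in re.findall(r"\(([^()]*)\)", body):
                core = re.sub(r"\[[^\]]*\]", "", path)
                for part in core.split("<"):
                    part = part.strip()
                    if part:
                        used_cells.add(int(part))

    for sid in sorted(used_surfaces - defined_surfaces):
        issues.append(f"surface {sid} referenced but not defined")
    for uid in sorted(used_universes - defined_universes):
        issues.append(f"universe {uid} referenced but not defined")
    for trn in sorted(used_trs - defined_trs):
        issues.append(f"transform {trn} referenced but not defined")
    for cid in sorted(used_cells - defined_cells):
        issues.append(f"cell {cid} referenced in a source path but not defined")
    for mid in sorted(defined_materials_used - defined_materials):
        issues.append(f"material {mid} used but not defined")
    return issues
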