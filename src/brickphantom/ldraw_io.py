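"""Read and write LDraw layout files.

LDraw is the open plain-text format for brick models (LDraw.org); layout
editors such as Bricklink Studio export it.  Only line type 1 (sub-file
reference) carries geometry::

    1 <colour> x y z a b c d e f g h i <part file>

with the rotation matrix given row-major (a b c / d e f / g h i) and acting
on column vectors.  Line type 0 (comments/meta) and line types 2-5
(edges/polygons) carry no placement information and are skipped.

Frame conventions: LDraw has -y pointing up; the phantom frame has +z up.
The axis change is ``(x, y, z)_ldraw -> (x, z, -y)_phantom``.  One LDraw
unit (LDU) is 0.4 mm, so the default scale is 25 LDU per cm and one lattice
unit is 68.75 LDU.  Part origins sit at the brick-local minimum corner;
positions are snapped to the lattice with a 0.01 cm tolerance.

The custom part catalog encodes brick type and source-hole assignment in
the part id (``uph_full.dat``, ``uph_full_s1.dat`` ... ``uph_half_s4.dat``),
which makes the one-source-per-brick rule structural.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .brick_model import (
    BrickTypeSpec,
    Layout,
    Orientation,
    Placement,
    footprint_delta,
    lattice_unit,
    make_brick_registry,
)
from .errors import LdrawParseError, OrientationError

log = logging.getLogger(__name__)

DEFAULT_SCALE = 25.0  # LDU per cm
SNAP_TOL_CM = 0.01

# change of basis: phantom = C @ ldraw
_C = np.array([[1, 0, 0], [0, 0, 1], [0, -1, 0]], dtype=int)
_C_INV = _C.T


@dataclass(frozen=True)
class LdrawRef:
    """A parsed line-type-1 record (positions in LDraw units)."""

    color: int
    pos: tuple[float, float, float]
    matrix: tuple[tuple[float, float, float], ...]
    part_id: str
    line_no: int = 0


def default_catalog() -> dict[str, tuple[str, int | None]]:
    """Part id -> (brick type, source hole).  Every brick type has one
    source-free part and four one-source parts."""
    catalog: dict[str, tuple[str, int | None]] = {}
    for tid in ("full", "half"):
        catalog[f"uph_{tid}.dat"] = (tid, None)
        for hole in range(1, 5):
            catalog[f"uph_{tid}_s{hole}.dat"] = (tid, hole)
    return catalog


def classify_part(
    part_id: str, catalog: Mapping[str, tuple[str, int | None]]
) -> tuple[str, int | None]:
    """Look up a part id; unknown ids raise naming the offending id."""
    try:
        return catalog[part_id]
    except KeyError:
        raise LdrawParseError(
            f"unknown part id {part_id!r}; known parts: "
            + ", ".join(sorted(catalog))
        ) from None


def convert_pose(
    ref: LdrawRef, scale: float = DEFAULT_SCALE, unit: float = 2.75
) -> tuple[tuple[int, int, int], Orientation]:
    """Map an LDraw pose to (anchor lattice cell, phantom orientation).

    The anchor is the cell holding the part origin (the brick's local
    minimum corner); for non-identity orientations the placement's
    minimum-corner index differs by :func:`footprint_delta`.  Positions
    must land on the lattice within 0.01 cm; matrices must round to a
    proper signed permutation.
    """
    return _convert_pose_unit(ref, scale, unit)


def _convert_pose_unit(
    ref: LdrawRef, scale: float, unit: float
) -> tuple[tuple[int, int, int], Orientation]:
    pos_cm = (_C @ np.array(ref.pos, dtype=float)) / scale
    anchor_f = pos_cm / unit
    anchor = np.rint(anchor_f).astype(int)
    residual = np.abs(anchor_f - anchor).max() * unit
    if residual > SNAP_TOL_CM:
        raise LdrawParseError(
            f"line {ref.line_no}: position {ref.pos} is {residual:.4f} cm off "
            f"the {unit} cm lattice (tolerance {SNAP_TOL_CM} cm)"
        )
    m_ldraw = np.array(ref.matrix, dtype=float)
    m_phantom = _C @ m_ldraw @ _C_INV
    try:
        orientation = Orientation.from_matrix(m_phantom)
    except OrientationError as exc:
        raise OrientationError(f"line {ref.line_no}: {exc}") from None
    return tuple(int(v) for v in anchor), orientation


def _parse_ref(fields: list[str], line_no: int) -> LdrawRef:
    try:
        color = int(fields[1])
        nums = [float(v) for v in fields[2:14]]
    except ValueError as exc:
        raise LdrawParseError(f"line {line_no}: malformed numeric field ({exc})")
    part_id = " ".join(fields[14:])
    return LdrawRef(
        color=color,
        pos=(nums[0], nums[1], nums[2]),
        matrix=(tuple(nums[3:6]), tuple(nums[6:9]), tuple(nums[9:12])),
        part_id=part_id,
        line_no=line_no,
    )


def parse_ldraw(
    text: str,
    catalog: Mapping[str, tuple[str, int | None]] | None = None,
    scale: float = DEFAULT_SCALE,
    registry: Mapping[str, BrickTypeSpec] | None = None,
) -> Layout:
    """Parse LDraw text into a :class:`Layout`.

    One placement per line-type-1 record whose part id is in the catalog
    (order preserved); comments and other line types are skipped with a
    debug log note.  Multi-model (MPD) documents are rejected.  Parsing is
    insensitive to line endings and repeated whitespace.
    """
    if catalog is None:
        catalog = default_catalog()
    if registry is None:
        registry = make_brick_registry()
    if scale <= 0:
        raise LdrawParseError(f"scale must be positive, got {scale}")
    unit = lattice_unit(registry)

    placements: list[Placement] = []
    n_models = 0
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        ltype = fields[0]
        if ltype == "0":
            if len(fields) >= 2 and fields[1].upper() == "FILE":
                n_models += 1
                if n_models > 1:
                    raise LdrawParseError(
                        f"line {line_no}: multi-model (MPD) documents are not "
                        "supported; export each model to its own file"
                    )
            continue
        if ltype != "1":
            log.debug("line %d: ignoring line type %s", line_no, ltype)
            continue
        if len(fields) < 15:
            raise LdrawParseError(
                f"line {line_no}: line-type-1 record needs 15 fields, "
                f"got {len(fields)}"
            )
        ref = _parse_ref(fields, line_no)
        brick, source_hole = classify_part(ref.part_id, catalog)
        anchor, orientation = _convert_pose_unit(ref, scale, unit)
        spec = registry[brick]
        index = np.array(anchor) + footprint_delta(orientation, spec.seg_counts)
        placements.append(
            Placement(
                pid=f"b{len(placements):03d}",
                brick=brick,
                index=tuple(int(v) for v in index),
                orientation=orientation,
                source_hole=source_hole,
            )
        )
    return Layout(placements=tuple(placements))


def _fmt(value: float) -> str:
    text = f"{value:.6f}".rstrip("0").rstrip(".")
    return text if text not in ("-0", "") else "0"


def write_ldraw(
    layout: Layout,
    catalog: Mapping[str, tuple[str, int | None]] | None = None,
    scale: float = DEFAULT_SCALE,
    registry: Mapping[str, BrickTypeSpec] | None = None,
    title: str = "brickphantom layout",
) -> str:
    """Serialise a layout to LDraw text; the exact inverse of
    :func:`parse_ldraw` placement-for-placement."""
    if catalog is None:
        catalog = default_catalog()
    if registry is None:
        registry = make_brick_registry()
    unit = lattice_unit(registry)
    parts = {v: k for k, v in catalog.items()}

    lines = [f"0 {title}", "0 !LDRAW_ORG Unofficial_Model"]
    for p in layout.placements:
        spec = registry[p.brick]
        anchor = np.array(p.index) - footprint_delta(p.orientation, spec.seg_counts)
        pos_cm = anchor.astype(float) * unit
        pos_ldu = (_C_INV @ pos_cm) * scale
        m_ldraw = _C_INV @ p.orientation.matrix @ _C
        part_id = parts[(p.brick, p.source_hole)]
        nums = " ".join(_fmt(v) for v in pos_ldu)
        mat = " ".join(str(int(v)) for v in m_ldraw.flatten())
        lines.append(f"1 16 {nums} {mat} {part_id}")
    return "\n".join(lines) + "\n"
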