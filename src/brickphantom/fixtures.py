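"""Canonical layout fixtures and random-layout generation.

The real phantom ships with canonical physique/posture layouts; their
exact brick arrangements are not public, so the fixtures here are frozen
package conventions that reproduce the documented brick counts.  The
``p70_stretcher`` fixture is the 70 kg configuration: 68 full and 4 half
bricks (solid volume 69 877.5 cm^3, i.e. 69.8775 kg at unit density)
arranged as a lying figure — feet, legs, torso, arms, shoulders, a rotated
head and half-brick caps — with six rod sources placed in the trunk and
head.
"""

from __future__ import annotations

import numpy as np

from .brick_model import (
    BrickTypeSpec,
    Layout,
    Orientation,
    Placement,
    all_orientations,
    build_segment_map,
    rot_z,
    segment_brick,
)
from .errors import FixtureError
from .ldraw_io import write_ldraw


def _placements(specs) -> Layout:
    return Layout(
        placements=tuple(
            Placement(
                pid=f"b{i:03d}",
                brick=brick,
                index=index,
                orientation=orientation,
                source_hole=source,
            )
            for i, (brick, index, orientation, source) in enumerate(specs)
        )
    )


def _single(brick: str) -> Layout:
    return _placements([(brick, (0, 0, 0), Orientation.identity(), None)])


def _mini_torso() -> Layout:
    """Six-brick smoke-test block: 4 full + 2 half, two rod sources."""
    ident = Orientation.identity()
    specs = [
        ("full", (0, 0, 0), ident, 2),
        ("full", (0, 4, 0), ident, None),
        ("full", (0, 0, 2), ident, None),
        ("full", (0, 4, 2), ident, None),
        ("half", (0, 0, 4), ident, None),
        ("half", (0, 4, 4), ident, 3),
    ]
    return _placements(specs)


def _p70_stretcher() -> Layout:
    """The 70 kg configuration in stretcher (lying) geometry:
    68 full + 4 half bricks."""
    ident = Orientation.identity()
    rz = rot_z(1)
    sources = {
        (30, 0, 4): 1,
        (30, 4, 4): 4,
        (36, 0, 2): 2,
        (36, 4, 2): 3,
    }
    specs = []
    # feet
    for y in (0, 4):
        specs.append(("full", (-6, y, 0), ident, None))
    # legs: four bricks long, two abreast, two layers
    for x in (0, 6, 12, 18):
        for y in (0, 4):
            for z in (0, 2):
                specs.append(("full", (x, y, z), ident, None))
    # torso: four long, two wide, four layers
    for x in (24, 30, 36, 42):
        for y in (0, 4):
            for z in (0, 2, 4, 6):
                specs.append(("full", (x, y, z), ident, sources.get((x, y, z))))
    # arms alongside the torso, two layers
    for x in (24, 30, 36):
        for y in (-4, 8):
            for z in (0, 2):
                specs.append(("full", (x, y, z), ident, None))
    # shoulders
    for y in (-4, 8):
        for z in (0, 2):
            specs.append(("full", (42, y, z), ident, None))
    # head: two rotated bricks (footprint 4 x 6), one with a source
    specs.append(("full", (48, 1, 0), rz, 1))
    specs.append(("full", (48, 1, 2), rz, None))
    # half bricks: chest caps and head caps (head caps rotated)
    specs.append(("half", (30, 0, 8), ident, 2))
    specs.append(("half", (30, 4, 8), ident, None))
    specs.append(("half", (48, 1, 4), rz, None))
    specs.append(("half", (48, 1, 5), rz, None))
    return _placements(specs)


FIXTURES = {
    "single_full": lambda: _single("full"),
    "single_half": lambda: _single("half"),
    "mini_torso": _mini_torso,
    "p70_stretcher": _p70_stretcher,
}


def fixture_layout(name: str) -> Layout:
    """The fixture as a :class:`Layout` object."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise FixtureError(
            f"unknown fixture {name!r}; available: "
            + ", ".join(sorted(FIXTURES))
        ) from None
    return builder()


def generate_canonical_layout(name: str) -> str:
    """The fixture serialised as deterministic LDraw text."""
    return write_ldraw(fixture_layout(name), title=f"brickphantom fixture {name}")


def random_layout(
    rng: np.random.Generator,
    n_bricks: int = 8,
    span: int = 10,
    p_half: float = 0.3,
    p_source: float = 0.4,
    registry=None,
) -> Layout:
    """A random collision-free layout (rejection placement on a bounded
    lattice); deterministic for a fixed generator state.  Used by property
    tests and useful for fuzzing downstream tooling."""
    from .brick_model import make_brick_registry

    reg = registry if registry is not None else make_brick_registry()
    orientations = all_orientations()
    occupied: set[tuple[int, int, int]] = set()
    placements: list[Placement] = []
    attempts = 0
    while len(placements) < n_bricks and attempts < 200 * n_bricks:
        attempts += 1
        brick = "half" if rng.random() < p_half else "full"
        orientation = orientations[int(rng.integers(len(orientations)))]
        index = tuple(int(v) for v in rng.integers(0, span, size=3))
        source = int(rng.integers(1, 5)) if rng.random() < p_source else None
        candidate = Placement(
            pid=f"b{len(placements):03d}",
            brick=brick,
            index=index,
            orientation=orientation,
            source_hole=source,
        )
        cells = {seg.cell for seg in segment_brick(candidate, reg)}
        if cells & occupied:
            continue
        occupied |= cells
        placements.append(candidate)
    return Layout(placements=tuple(placements))
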