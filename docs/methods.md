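# Methods

## Model

The phantom is a set of rigid bricks placed on a cubic lattice of unit
`u = 2.75 cm`, the smallest dimension occurring in the geometry (the
half-brick thickness). Brick types:

| type | dimensions (cm)    | segments      |
|------|--------------------|---------------|
| full | 16.5 × 11 × 5.5    | 6 × 4 × 2 = 48|
| half | 16.5 × 11 × 2.75   | 6 × 4 × 1 = 24|

Frames and conventions (the physical phantom fixes none of these, so they
are package conventions, chosen once):

* phantom frame: right-handed, z the vertical stacking axis; brick-local
  axes x (16.5 cm), y (11 cm), z (thickness), brick spanning `[0, dims]`
  with the source drill holes on the front face z = 0;
* lattice cells are half-open `[i·u, (i+1)·u)` with 0-based, possibly
  negative indices; a placement's index is the minimum-corner cell of its
  rotated footprint — this makes occupancy unambiguous;
* orientations are the 24 proper signed-permutation matrices
  (det = +1); reflections are rejected since a physical brick cannot be
  mirrored. Segmentation works in doubled integer coordinates
  (2a+1, 2b+1, 2c+1), so rotated cell assignment is exact integer
  arithmetic with no floating-point rounding.

## Drill holes and rod sources

The real bricks' drill dimensions are not public; the defaults below are
explicit conventions, all overridable through the YAML configuration:

| parameter            | default            | note |
|----------------------|--------------------|------|
| source-hole offsets  | (±4.125, ±1.375) cm from the front-face centre | puts every hole axis exactly on a lattice-cell centre |
| source-hole radius   | 0.4 cm             | through hole (depth = brick thickness) |
| rod radius           | 0.35 cm            | leaves an annular air gap in the hole |
| rod plug length      | 0 cm               | active length = brick thickness |
| connector holes      | r 0.3 cm, depth 1.0 cm, one per y-face | blind holes for metal connectors |
| polyethylene density | 0.95 g/cm³         | CH₂ |
| air density          | 1.205 × 10⁻³ g/cm³ | |

The hole offsets deserve a word: placing holes on quarter-points of the
face (y-offset ±2.75 cm) would put the hole axes exactly on lattice
planes, splitting every rod cylinder across two lattice columns. The
chosen ±1.375 cm y-offset keeps each rod wholly inside one column of
cells, so the per-segment source split is purely axial and the
bounding-box rejection efficiency is exactly π/4.

With plug length 0 the half-brick active length (2.75 cm) is exactly half
the full-brick one (5.5 cm), so the per-source weighting rule — full : half
= 1 : ½ — coincides with active-length-proportional weighting. The rule is
implemented as weight ∝ brick thickness, which reduces to 1 : ½ for the
default registry. Rod active and plug volumes are air-filled cells by
default (the capsule is omitted; only polyethylene is a documented
material of the physical phantom).

## Source sampling

For each placed source, the active cylinder `[0, L]` along the hole axis
is clipped against the lattice planes; each traversed segment receives
probability `weight × (contained length) / L`, giving a uniform spatial
density within each source and the 1 : ½ full/half rule across sources.
Probabilities are normalised to 1 (checked to 1 × 10⁻¹²). The emitted
cards follow the cell-rejection pattern: `SI1 L` lists four-level cell
paths (rod-core cell < segment fill cell < lattice element [i j k] <
container), `SP1` the probabilities, and per-entry dependent `SI/SP`
pairs sample x, y, z uniformly over the segment-clipped bounding box of
the cylinder; MCNP's rejection against the source cell then yields the
uniform cylindrical distribution. Clipping the box per segment (rather
than per rod) means each entry can only produce points in its own cell.

## Deck structure and numbering

One brick *variant* is a (type, occupied source hole) pair; only variants
present in the layout are emitted. Surfaces depend on type alone and are
shared across variants; a hole's rod-core cell exists in every variant
(air-filled when unoccupied), so the cell count is independent of the
source assignment. Segment universes clip the brick universe to one
`(2.75 cm)³` cube via a translated `fill`. Lattice element [0,0,0] is the
cube centred on the lattice-universe origin, so per-element `u (tr)`
transforms rotate about the element centre; the container cell fills the
lattice universe shifted by u/2 to align world cells with elements. TR
cards carry zero displacement and the placement rotation row-major
(main = B · universe coordinates); at most 24 are emitted, identity
omitted.

Id bases (deterministic, configurable): world/room/graveyard cells 1–3,
background air cells 5–6, lattice cell and universe 10, brick universes
from 50, template cells from 100 (stride 20 per variant), segment
universes from 200 (stride 200 per variant — the two plain variants land
on 200/400), segment cells from 10000, surfaces from 1000 (stride 100 per
type), TR cards from 900, materials m1 (polyethylene) and m2 (air).

Cards are wrapped at 78 characters with 5-blank continuations, token
boundaries preserved. Every emitted deck passes an internal linter that
re-parses the text and checks that all referenced surfaces, cells,
universes, transforms and materials are defined and that the FILL array
length equals the product of its index ranges; `emit_deck` refuses to
return a deck that fails it. Emission is a pure function of
(layout, registry, config): identical inputs give identical bytes.

## LDraw conventions

LDraw's −y axis points up; the axis change is
(x, y, z)_ldraw → (x, z, −y)_phantom. The default scale is the standard
25 LDU/cm (1 LDU = 0.4 mm), one lattice unit = 68.75 LDU. Part origins
sit at the brick's local minimum corner; positions snap to the lattice
with a 0.01 cm tolerance and matrices round to signed permutations with
the same per-entry tolerance — anything farther is a hard error, not a
silent snap. Colours are read and ignored; MPD multi-model documents are
rejected. Writing then parsing a layout is an exact identity,
placement for placement.

## Voxel oracle

The oracle rasterises the analytical geometry (boxes minus hole
cylinders, plus rod active/plug cylinders) by labelling each voxel from
its centre point, with no supersampling. Centre labelling has a
first-order error bound — |voxel volume − analytic volume| ≤ region
surface area × voxel edge — which the tests check at 0.275 and 0.1375 cm
to confirm convergence; at 0.06875 cm the rod active volume is within 2 %
of π r² L. Because brick faces lie on lattice planes, total brick volume
is exact at any dividing resolution. Sampling reproduces the SDEF scheme
literally: entry drawn from the SP probabilities, position uniform in the
entry's box, rejection against the rod cylinder; it is bit-reproducible
for a fixed seed (default 20210828) and aborts if the efficiency falls
below 10 %. Grids can be exported as per-slice CSV files for inspection.

## Fixtures and synthetic layouts

The canonical layouts shipped with the physical phantom are not public;
the bundled fixtures are frozen conventions. `p70_stretcher` reproduces
the documented 70 kg configuration — 68 full + 4 half bricks, solid
volume 69 877.5 cm³ — as a lying figure (feet, double-layer legs,
four-layer torso, arms, shoulders, a 90°-rotated head, half-brick chest
and head caps) with six rod sources in trunk and head. `mini_torso` is a
six-brick smoke test with one full-brick and one half-brick source.
`random_layout` generates seeded collision-free layouts (rejection
placement, all 24 orientations, optional sources) for property tests and
fuzzing.

What the fixtures do *not* model: the physical phantom's connector
hardware and source capsules, real drill positions, and non-lattice
postures. Passing tests therefore demonstrate the correctness of the
geometry and source bookkeeping, not dosimetric agreement with any physical
measurement; that comparison requires running the generated decks in MCNP
against calibration data.

## Problem sizes

The test suite and the acceptance script run deterministic cases at desk
scale: single bricks for segment counts and volumes, the 72-brick 70 kg
layout for deck emission (8352-element FILL array, 3360 brick segments),
200 seeded random layouts of up to ~12 bricks for the round-trip and
occupancy properties, 10⁵ sample points for the binomial checks of the
source distribution, and voxel grids up to 240 × 160 × 80 (0.06875 cm
over one brick).

## Known limitations

* One rod source per brick (encoded in the part catalog); several sources
  per brick require one deck per source, combined afterwards.
* Lattice-only placement; inclined assemblies are composed manually from
  several generated decks.
* The SDEF path syntax and TR matrix convention target MCNP 6.2; other
  dialects may need adaptation.
* `layout_mass` uses the solid-brick approximation (hole voids ignored),
  since hole dimensions are configuration, not documented fact.
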