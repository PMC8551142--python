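# brickphantom

Generate ready-to-run MCNP6 input decks for the Saint Petersburg brick
phantom — the stackable high-density-polyethylene calibration phantom
(known as UPh, Igor, Olga or Irina) used at whole-body counting
facilities — from LDraw layout files produced with ordinary brick-design
software.

## The problem

Whole-body counters are calibrated with physical brick phantoms: full
bricks of 16.5 × 11 × 5.5 cm and half bricks of 16.5 × 11 × 2.75 cm, each
with four drill holes in the front face for sealed rod-shaped radionuclide
sources. To compare such calibrations with Monte-Carlo simulations (and
with anthropomorphic computational phantoms), the assembled brick layout
must be reproduced in a transport code as an *analytical* geometry — exact
boxes and cylinders, not voxels.

`brickphantom` does this conversion. A user lays out bricks in any
LDraw-capable editor; the package

1. parses the LDraw file (positions, 3×3 rotation matrices, custom part
   ids that encode brick type and source-hole choice),
2. snaps every brick onto the 2.75 cm cubic lattice — 2.75 cm being the
   smallest dimension in the geometry — and decomposes each full brick
   into 6 × 4 × 2 = 48 and each half brick into 6 × 4 = 24 cubic segments,
3. emits an MCNP deck: rpp/rcc template geometry per brick variant,
   universe/fill segment decomposition, a single fully-specified `LAT=1`
   lattice with per-element transforms (≤ 24 shared `TR` cards), and
4. writes an `SDEF` source definition that samples each rod source with
   uniform spatial density, splits it over its lattice segments by
   contained active length, and weights full-brick sources : half-brick
   sources as 1 : ½ (cell rejection + source probability cards).

A built-in voxelization/sampling oracle verifies the geometry and the
source distribution numerically without running MCNP.

## Worked example

```sh
brickphantom fixture mini_torso -o mini.ldr
brickphantom build mini.ldr -o mini.i
```

prints the layout summary

```
bricks:  4 full, 2 half
sources: 1 in full bricks, 1 in half bricks
lattice extents: 6 x 8 x 5 cells (origin cell (0, 0, 0))
occupied cells: 240
solid mass: 4.7417 kg at 0.95 g/cm3 (holes ignored)
collisions: none
```

and writes a complete deck whose first cards are

```
Brick phantom: 4 full + 2 half bricks (auto-generated deck)
1 0 -2 imp:p=1 fill=10 (1.375 1.375 1.375)
2 2 -0.001205 -1 2 imp:p=1 $ room air
3 0 1 imp:p=0 $ graveyard
10 0 -3 lat=1 u=10 imp:p=1 fill=0:5 0:7 0:4 400 401 402 403 404 405 406 407
     408 409 410 411 412 413 414 415 416 417 418 419 420 421 422 423 200 201
...
```

240 occupied cells is exactly 4·48 + 2·24; the FILL array lists one
segment universe per lattice element. Photon energy and history count in
the deck are placeholders for the user to adapt, as are detectors and
tallies, which are deliberately out of scope.

From Python, the same pipeline and the source arithmetic directly
(`python examples/source_probabilities.py`):

```
b000: full brick, hole 1, active 5.5 cm, weight 1.0
b001: half brick, hole 1, active 2.75 cm, weight 0.5

  b000 cell (1, 1, 0): probability 0.333333 (active span 0.000..2.750 cm)
  b000 cell (1, 1, 1): probability 0.333333 (active span 2.750..5.500 cm)
  b001 cell (7, 1, 0): probability 0.333333 (active span 0.000..2.750 cm)

sum of probabilities: 1.0
```

The full-brick source (weight 1) splits evenly over its two segments and
the half-brick source (weight ½) occupies one — three SDEF entries of ⅓
each. The `examples/` directory holds one short script per capability:
deck building, source probabilities, and the voxel oracle.

The bundled canonical layout `p70_stretcher` is the 70 kg configuration in
lying (stretcher) geometry: 68 full + 4 half bricks, 69.8775 kg of solid
brick volume at unit density.

## Scope

The generator covers lattice-aligned layouts (90° orientations) with at
most one rod source per brick, matching the physical phantom's workflow;
inclined assemblies are composed manually from several generated decks.
Detector models, tallies and MCNP execution are out of scope.
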