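"""Rod-source collection, the 1 : 1/2 probability rule, per-segment
splitting and SDEF emission."""

import numpy as np
import pytest

from brickphantom import (
    GeometryError,
    Layout,
    Orientation,
    Placement,
    build_segment_map,
    build_source_distribution,
    collect_sources,
    make_brick_registry,
    random_layout,
    rot_z,
    segment_fractions,
    source_weights,
)
from brickphantom.config import PhantomConfig, RodConfig
from brickphantom.mcnp_writer import make_plan
from brickphantom.source_builder import emit_sdef

IDENT = Orientation.identity()


def place(brick, index, orientation=IDENT, source=None, pid="b000"):
    return Placement(pid=pid, brick=brick, index=index,
                     orientation=orientation, source_hole=source)


class TestCollect:
    def test_no_sources(self, registry):
        assert collect_sources(Layout((place("full", (0, 0, 0)),)), registry) == []

    def test_identity_pose(self, registry):
        (rec,) = collect_sources(
            Layout((place("full", (0, 0, 0), source=1),)), registry
        )
        hole = registry["full"].source_hole(1)
        assert rec.axis == (0, 0, 1)
        assert rec.base == hole.center  # world == local at the origin
        assert rec.active_length == 5.5
        assert rec.weight == 1.0

    def test_rotated_pose(self, registry):
        """A 90-degree z-rotation maps the hole position accordingly and
        keeps the axis vertical."""
        (rec,) = collect_sources(
            Layout((place("full", (0, 0, 0), rot_z(1), source=1),)), registry
        )
        hole = registry["full"].source_hole(1)
        # rotated footprint is 11 x 16.5 cm; local (x, y) -> world (11 - y, x)
        assert rec.axis == (0, 0, 1)
        assert rec.base.x == pytest.approx(11.0 - hole.center.y)
        assert rec.base.y == pytest.approx(hole.center.x)

    def test_half_brick_weight(self, registry):
        (rec,) = collect_sources(
            Layout((place("half", (0, 0, 0), source=2),)), registry
        )
        assert rec.weight == 0.5


class TestWeights:
    def test_single_source(self, registry):
        recs = collect_sources(
            Layout((place("full", (0, 0, 0), source=1),)), registry
        )
        assert source_weights(recs, registry).tolist() == [1.0]

    def test_full_plus_half(self, registry):
        layout = Layout((
            place("full", (0, 0, 0), source=1, pid="a"),
            place("half", (6, 0, 0), source=1, pid="b"),
        ))
        w = source_weights(collect_sources(layout, registry), registry)
        assert w == pytest.approx([2 / 3, 1 / 3])

    def test_two_full_one_half(self, registry):
        layout = Layout((
            place("full", (0, 0, 0), source=1, pid="a"),
            place("full", (6, 0, 0), source=2, pid="b"),
            place("half", (12, 0, 0), source=3, pid="c"),
        ))
        w = source_weights(collect_sources(layout, registry), registry)
        assert w == pytest.approx([0.4, 0.4, 0.2])

    def test_empty_records_rejected(self, registry):
        with pytest.raises(GeometryError, match="no sources"):
            source_weights([], registry)


class TestSegmentFractions:
    def test_full_brick_symmetric_split(self, registry):
        layout = Layout((place("full", (0, 0, 0), source=1),))
        seg_map = build_segment_map(layout, registry)
        (rec,) = collect_sources(layout, registry)
        parts = segment_fractions(rec, seg_map, registry)
        assert [share for *_, share in parts] == pytest.approx([0.5, 0.5])
        assert [cell[2] for cell, *_ in parts] == [0, 1]

    def test_half_brick_single_segment(self, registry):
        layout = Layout((place("half", (0, 0, 0), source=1),))
        seg_map = build_segment_map(layout, registry)
        (rec,) = collect_sources(layout, registry)
        parts = segment_fractions(rec, seg_map, registry)
        assert len(parts) == 1
        assert parts[0][3] == pytest.approx(1.0)

    def test_partial_active_length(self):
        """Active length 4.125 cm from the front face splits 2:1 over the
        two traversed segments."""
        cfg = PhantomConfig(rod=RodConfig(radius=0.35, plug_length=1.375))
        reg = make_brick_registry(cfg)
        assert reg["full"].rod.active_length == 4.125
        layout = Layout((place("full", (0, 0, 0), source=1),))
        seg_map = build_segment_map(layout, reg)
        (rec,) = collect_sources(layout, reg)
        shares = [share for *_, share in segment_fractions(rec, seg_map, reg)]
        assert shares == pytest.approx([2 / 3, 1 / 3])

    def test_shares_sum_to_one_for_random_sources(self, registry, rng):
        for _ in range(30):
            layout = random_layout(rng, n_bricks=6, p_source=1.0)
            seg_map = build_segment_map(layout, registry)
            for rec in collect_sources(layout, registry):
                shares = [s for *_, s in segment_fractions(rec, seg_map, registry)]
                assert sum(shares) == pytest.approx(1.0, abs=1e-12)

    def test_rod_leaving_its_brick_rejected(self, registry):
        layout = Layout((place("full", (0, 0, 0), source=1),))
        seg_map = build_segment_map(layout, registry)
        (rec,) = collect_sources(layout, registry)
        import dataclasses

        stretched = dataclasses.replace(rec, active_length=8.0)
        with pytest.raises(GeometryError, match="outside its brick"):
            segment_fractions(stretched, seg_map, registry)


class TestDistributionAndSdef:
    def test_single_full_source_two_entries(self, registry, config):
        layout = Layout((place("full", (0, 0, 0), source=1),))
        plan = make_plan(layout, registry, config)
        records, dist = build_source_distribution(layout, registry, plan=plan)
        assert [e.probability for e in dist.entries] == pytest.approx([0.5, 0.5])
        cards = emit_sdef(records, dist, plan, config)
        sp1 = next(c for c in cards if c.startswith("sp1"))
        assert sp1.split()[1:] == ["0.5", "0.5"]

    def test_full_plus_half_three_equal_entries(self, registry, config):
        layout = Layout((
            place("full", (0, 0, 0), source=1, pid="a"),
            place("half", (6, 0, 0), source=1, pid="b"),
        ))
        plan = make_plan(layout, registry, config)
        _, dist = build_source_distribution(layout, registry, plan=plan)
        assert dist.probabilities == pytest.approx([1 / 3, 1 / 3, 1 / 3])

    def test_half_source_mass_is_half_of_full(self, registry, rng):
        """The phantom-level invariant: for any layout, the total probability
        of every half-brick source is exactly half that of every full-brick
        source."""
        for _ in range(20):
            layout = random_layout(rng, n_bricks=8, p_source=0.8)
            records, dist = build_source_distribution(layout, registry)
            if not records:
                continue
            totals = {}
            for e in dist.entries:
                totals[e.pid] = totals.get(e.pid, 0.0) + e.probability
            by_type = {r.pid: r.brick for r in records}
            fulls = [v for pid, v in totals.items() if by_type[pid] == "full"]
            halves = [v for pid, v in totals.items() if by_type[pid] == "half"]
            for f in fulls:
                assert f == pytest.approx(fulls[0], abs=1e-12)
            for h in halves:
                if fulls:
                    assert h == pytest.approx(fulls[0] / 2, abs=1e-12)

    def test_probabilities_normalized_tightly(self, registry, rng):
        for _ in range(20):
            layout = random_layout(rng, n_bricks=10, p_source=0.7)
            _, dist = build_source_distribution(layout, registry)
            if dist.entries:
                assert abs(dist.probabilities.sum() - 1.0) <= 1e-12

    def test_sdef_card_structure(self, registry, config):
        layout = Layout((place("full", (0, 0, 0), source=2),))
        plan = make_plan(layout, registry, config)
        records, dist = build_source_distribution(layout, registry, plan=plan)
        cards = emit_sdef(records, dist, plan, config)
        assert cards[0].startswith("sdef par=2 cel=d1")
        si1 = next(c for c in cards if c.startswith("si1"))
        assert si1.count("<") == 3 * len(dist.entries)  # 4-level paths
        # one dependent x/y/z distribution pair per entry
        assert sum(c.startswith("si") for c in cards) == 1 + 3 * len(dist.entries)

    def test_entry_boxes_clip_to_cells(self, registry):
        layout = Layout((place("full", (0, 0, 0), source=1),))
        _, dist = build_source_distribution(layout, registry)
        for e in dist.entries:
            lo, hi = e.bbox
            for d in range(3):
                assert hi[d] - lo[d] <= 2.75 + 1e-12
            assert np.floor(((np.array(lo) + np.array(hi)) / 2) / 2.75).astype(
                int
            ).tolist() == list(e.cell)
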