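"""Voxel rasterization oracle and source-sampling validation."""

import numpy as np
import pytest
from scipy import stats

from brickphantom import (
    CollisionError,
    GeometryError,
    Label,
    Layout,
    Orientation,
    Placement,
    build_source_distribution,
    sample_source_points,
    volume_report,
    voxelize,
)

IDENT = Orientation.identity()


def place(brick, index, orientation=IDENT, source=None, pid="b000"):
    return Placement(pid=pid, brick=brick, index=index,
                     orientation=orientation, source_hole=source)


def analytic_volumes(registry, brick, source_hole):
    """Closed-form region volumes of one brick (cm^3)."""
    spec = registry[brick]
    box = spec.dims[0] * spec.dims[1] * spec.dims[2]
    holes = sum(np.pi * h.radius**2 * h.depth for h in spec.source_holes)
    conns = sum(np.pi * h.radius**2 * h.depth for h in spec.connector_holes)
    active = plug = 0.0
    if source_hole is not None:
        rod = spec.rod
        active = np.pi * rod.radius**2 * rod.active_length
        plug = np.pi * rod.radius**2 * rod.plug_length
    return {
        Label.POLYETHYLENE: box - holes - conns,
        Label.HOLE_VOID: holes + conns - active - plug,
        Label.SOURCE_ACTIVE: active,
        Label.SOURCE_PLUG: plug,
    }


class TestVoxelize:
    def test_empty_layout_all_air(self, registry):
        grid = voxelize(Layout(()), registry, 0.275)
        assert grid.labels.size == 0

    def test_misfit_resolution_rejected(self, registry):
        with pytest.raises(GeometryError):
            voxelize(Layout((place("full", (0, 0, 0)),)), registry, 0.3)

    def test_grid_aligned_box_volume_exact(self, registry):
        """The total brick volume (all non-air labels) is exact at any
        dividing resolution because the brick faces lie on voxel
        boundaries: 998.25 cm^3 (full) and 499.125 cm^3 (half)."""
        grid = voxelize(Layout((place("full", (0, 0, 0)),)), registry, 0.275)
        vols = volume_report(grid)
        non_air = sum(v for label, v in vols.items() if label != Label.AIR)
        assert non_air == pytest.approx(998.25, abs=1e-9)
        grid_half = voxelize(Layout((place("half", (0, 0, 0)),)), registry, 0.275)
        vols_half = volume_report(grid_half)
        non_air_half = sum(v for l, v in vols_half.items() if l != Label.AIR)
        assert non_air_half == pytest.approx(499.125, abs=1e-9)

    def test_label_volumes_partition_bounding_volume(self, registry):
        layout = Layout((place("full", (0, 0, 0), source=3),))
        grid = voxelize(layout, registry, 0.1375)
        vols = volume_report(grid)
        total = grid.labels.size * grid.resolution**3
        assert sum(vols.values()) == pytest.approx(total, rel=1e-12)

    def test_source_active_volume_fine_grid(self, registry):
        """Rod active volume within 2 % of pi r^2 L at 0.06875 cm."""
        layout = Layout((place("full", (0, 0, 0), source=1),))
        vols = volume_report(voxelize(layout, registry, 0.06875))
        expected = np.pi * 0.35**2 * 5.5
        assert vols[Label.SOURCE_ACTIVE] == pytest.approx(expected, rel=0.02)

    @pytest.mark.parametrize("resolution", [0.275, 0.1375])
    def test_first_order_error_bound(self, registry, resolution):
        """Every region's voxel volume is within (surface area x edge
        length) of the analytic value, at two resolutions."""
        layout = Layout((place("full", (0, 0, 0), source=1),))
        vols = volume_report(voxelize(layout, registry, resolution))
        expected = analytic_volumes(registry, "full", 1)
        spec = registry["full"]
        areas = {
            Label.POLYETHYLENE: 2 * (16.5 * 11 + 16.5 * 5.5 + 11 * 5.5)
            + sum(2 * np.pi * h.radius * h.depth for h in spec.holes),
            Label.HOLE_VOID: sum(
                2 * np.pi * h.radius * (h.depth + h.radius) for h in spec.holes
            )
            + 2 * np.pi * spec.rod.radius * (spec.rod.active_length + 0.7),
            Label.SOURCE_ACTIVE: 2 * np.pi * spec.rod.radius
            * (spec.rod.active_length + spec.rod.radius),
        }
        for label, area in areas.items():
            assert abs(vols[label] - expected[label]) <= area * resolution

    def test_rotation_preserves_volumes(self, registry):
        from brickphantom import rot_y

        upright = volume_report(
            voxelize(Layout((place("full", (0, 0, 0), source=2),)), registry, 0.1375)
        )
        rotated = volume_report(
            voxelize(
                Layout((place("full", (0, 0, 0), rot_y(1), source=2),)),
                registry, 0.1375,
            )
        )
        for label in (Label.POLYETHYLENE, Label.SOURCE_ACTIVE):
            assert rotated[label] == pytest.approx(upright[label], rel=0.02)

    def test_overlap_raises(self, registry):
        layout = Layout((
            place("full", (0, 0, 0), pid="a"),
            place("full", (0, 0, 0), pid="b"),
        ))
        with pytest.raises(CollisionError):
            voxelize(layout, registry, 0.275)


class TestSampling:
    def test_points_inside_cylinder(self, registry):
        layout = Layout((place("full", (0, 0, 0), source=1),))
        records, dist = build_source_distribution(layout, registry)
        points, counts = sample_source_points(dist, records, 1000, seed=11)
        assert points.shape == (1000, 3)
        rec = records[0]
        rel = points - rec.base.as_array()
        t = rel @ np.array(rec.axis, dtype=float)
        radial2 = (rel**2).sum(axis=1) - t**2
        assert np.all((t >= 0) & (t <= rec.active_length))
        assert np.all(radial2 <= rec.radius**2 + 1e-12)

    def test_symmetric_split_within_3_sigma(self, registry):
        layout = Layout((place("full", (0, 0, 0), source=1),))
        records, dist = build_source_distribution(layout, registry)
        n = 100_000
        _, counts = sample_source_points(dist, records, n, seed=20210828)
        sigma = np.sqrt(n * 0.5 * 0.5)
        assert abs(counts[0] - n / 2) <= 3 * sigma

    def test_full_half_weighting_within_3_sigma(self, registry):
        layout = Layout((
            place("full", (0, 0, 0), source=1, pid="a"),
            place("half", (6, 0, 0), source=1, pid="b"),
        ))
        records, dist = build_source_distribution(layout, registry)
        n = 100_000
        _, counts = sample_source_points(dist, records, n, seed=20210828)
        half_count = sum(
            c for e, c in zip(dist.entries, counts) if e.pid == "b"
        )
        p = 1 / 3
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(half_count - n * p) <= 3 * sigma

    def test_axial_distribution_uniform(self, registry):
        """Kolmogorov-Smirnov test of the axial coordinate against the
        uniform law at alpha = 0.01."""
        layout = Layout((place("full", (0, 0, 0), source=4),))
        records, dist = build_source_distribution(layout, registry)
        points, _ = sample_source_points(dist, records, 20_000, seed=5)
        rec = records[0]
        t = (points - rec.base.as_array()) @ np.array(rec.axis, dtype=float)
        result = stats.kstest(t / rec.active_length, "uniform")
        assert result.pvalue > 0.01

    def test_reproducible_bit_for_bit(self, registry):
        layout = Layout((place("full", (0, 0, 0), source=1),))
        records, dist = build_source_distribution(layout, registry)
        p1, c1 = sample_source_points(dist, records, 5000, seed=42)
        p2, c2 = sample_source_points(dist, records, 5000, seed=42)
        assert np.array_equal(p1, p2) and np.array_equal(c1, c2)

    def test_sampled_points_in_source_voxels(self, registry):
        """Every sampled point lands in a voxel labelled source-active at
        fine resolution (modulo the half-voxel rasterization skin)."""
        layout = Layout((place("full", (0, 0, 0), source=1),))
        grid = voxelize(layout, registry, 0.06875)
        records, dist = build_source_distribution(layout, registry)
        points, _ = sample_source_points(dist, records, 2000, seed=3)
        idx = np.floor(
            (points - np.array(grid.origin)) / grid.resolution
        ).astype(int)
        labels = grid.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
        frac_active = np.mean(labels == int(Label.SOURCE_ACTIVE))
        assert frac_active > 0.9  # boundary voxels may be labelled hole void
        assert np.all(
            (labels == int(Label.SOURCE_ACTIVE)) | (labels == int(Label.HOLE_VOID))
        )

    def test_invalid_inputs(self, registry):
        layout = Layout((place("full", (0, 0, 0), source=1),))
        records, dist = build_source_distribution(layout, registry)
        with pytest.raises(GeometryError):
            sample_source_points(dist, records, 0)
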