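"""Circularity, validity, admin matching, overlap relations, annuli."""

import math

import numpy as np
import pandas as pd
import pytest
import shapely
import shapely.affinity
from shapely.geometry import Point, Polygon

from ldis import PipelineConfig
from ldis._geodesy import LocalMetricFrame, buffer_metric, geodesic_area_km2
from ldis.geometry_integrity import (
    classify_overlaps,
    compute_circularity,
    compute_flags,
    flag_perfect_circle,
    make_annulus,
    match_admin_area,
    validate_geometry,
)


class TestValidity:
    def test_unit_square_valid(self):
        assert validate_geometry(Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]))

    def test_bowtie_invalid(self):
        assert not validate_geometry(Polygon([(0, 0), (1, 1), (1, 0), (0, 1)]))

    def test_collinear_zero_area_invalid(self):
        # shoelace area of three collinear points is exactly 0
        assert not validate_geometry(Polygon([(0, 0), (1, 1), (2, 2)]))

    def test_point_and_empty_are_not_valid_polygons(self):
        assert not validate_geometry(Point(0, 0))
        assert not validate_geometry(None)


class TestCircularity:
    def test_disc_is_one(self, frame):
        disc = frame.to_wgs84(Point(0, 0).buffer(500.0, quad_segs=64))
        assert compute_circularity(disc) == pytest.approx(1.0, abs=0.01)

    def test_unit_square_is_pi_over_4(self, unit_square_km):
        assert compute_circularity(unit_square_km) == pytest.approx(math.pi / 4, rel=1e-4)

    def test_thin_rectangle_closed_form(self, metric_polygon):
        # 10 x 0.1 (km): 4*pi*A/P^2 = 4*pi*1 / 20.2^2
        rect = metric_polygon([(0, 0), (10_000, 0), (10_000, 100), (0, 100)])
        assert compute_circularity(rect) == pytest.approx(4 * math.pi / 20.2**2, rel=1e-3)

    @pytest.mark.parametrize("dx_m, angle_deg, scale", [
        (2000.0, 0.0, 1.0), (0.0, 37.0, 1.0), (500.0, 90.0, 3.0), (0.0, 0.0, 0.2),
    ])
    def test_invariance_under_rigid_motion_and_scaling(self, frame, dx_m, angle_deg, scale):
        hexagon = Polygon([(600 * math.cos(a), 400 * math.sin(a))
                           for a in np.linspace(0, 2 * math.pi, 7)[:-1]])
        base = compute_circularity(frame.to_wgs84(hexagon))
        moved = shapely.affinity.rotate(
            shapely.affinity.scale(hexagon, scale, scale), angle_deg
        )
        moved = shapely.affinity.translate(moved, dx_m, 0)
        assert compute_circularity(frame.to_wgs84(moved)) == pytest.approx(base, rel=1e-4)

    def test_invalid_geometry_raises(self):
        with pytest.raises(ValueError):
            compute_circularity(Polygon([(0, 0), (1, 1), (1, 0), (0, 1)]))


class TestPerfectCircleFlag:
    def test_thresholding(self, cfg):
        assert flag_perfect_circle(0.99, cfg)
        assert not flag_perfect_circle(math.pi / 4, cfg)

    def test_point_buffer_disc_always_flagged(self, cfg):
        disc = buffer_metric(Point(36.8, -1.3), cfg.point_buffer_m)
        assert flag_perfect_circle(compute_circularity(disc), cfg)


class TestAdminMatch:
    @pytest.fixture
    def admins(self, metric_polygon):
        return pd.DataFrame({
            "admin_id": ["A", "B"],
            "name": ["A", "B"],
            "level": [2, 2],
            "geometry": [
                metric_polygon([(0, 0), (2000, 0), (2000, 1500), (0, 1500)]),
                metric_polygon([(9000, 0), (12_000, 0), (12_000, 2000), (9000, 2000)]),
            ],
        })

    def test_identical_geometry_matches(self, admins, cfg):
        ok, aid = match_admin_area(admins["geometry"][0], admins, cfg)
        assert ok and aid == "A"

    def test_every_admin_matches_its_own_table(self, admins, cfg):
        for geom in admins["geometry"]:
            assert match_admin_area(geom, admins, cfg)[0]

    def test_half_coverage_does_not_match(self, admins, cfg, metric_polygon):
        half = metric_polygon([(0, 0), (1000, 0), (1000, 1500), (0, 1500)])
        assert match_admin_area(half, admins, cfg) == (False, None)

    def test_concentric_shrink_to_985_matches(self, admins, cfg):
        g = shapely.affinity.scale(
            admins["geometry"][0], math.sqrt(0.985), math.sqrt(0.985)
        )
        # oracle: clipped-overlap ratios both exceed 0.98
        inter = geodesic_area_km2(g.intersection(admins["geometry"][0]))
        assert inter / geodesic_area_km2(g) > 0.98
        assert inter / geodesic_area_km2(admins["geometry"][0]) > 0.98
        ok, aid = match_admin_area(g, admins, cfg)
        assert ok and aid == "A"


def _table(frame, geoms):
    return pd.DataFrame({
        "site_id": [f"s{i}" for i in range(len(geoms))],
        "geometry_derived": [frame.to_wgs84(g) for g in geoms],
    })


class TestClassifyOverlaps:
    def test_identical_polygons_are_duplicates(self, frame):
        sq = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
        out = classify_overlaps(_table(frame, [sq, Polygon(sq)]))
        # duplicates are recorded as mutual nesting
        assert out["nested_in"][0] == ["s1"] and out["nested_in"][1] == ["s0"]
        assert out["contains_small_polygon"][0] == ["s1"]
        assert out["intersecting_with"][0] == []

    def test_quarter_containment_is_nesting(self, frame):
        big = Polygon([(0, 0), (2000, 0), (2000, 2000), (0, 2000)])
        small = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
        out = classify_overlaps(_table(frame, [small, big]))
        assert out["nested_in"][0] == ["s1"]       # I/|small| = 1 > 0.95
        assert out["contains_small_polygon"][1] == ["s0"]  # I/|big| = 0.25
        assert out["nested_in"][1] == []

    def test_thirty_percent_overlap_is_plain_intersection(self, frame):
        a = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
        b = shapely.affinity.translate(a, 700.0)
        out = classify_overlaps(_table(frame, [a, b]))
        assert out["intersecting_with"][0] == ["s1"]
        assert out["intersecting_with"][1] == ["s0"]
        assert out["nested_in"][0] == [] and out["nested_in"][1] == []

    def test_invalid_geometry_skipped_and_flagged(self, frame):
        bowtie = Polygon([(0, 0), (1000, 1000), (1000, 0), (0, 1000)])
        sq = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
        out = classify_overlaps(_table(frame, [bowtie, sq]))
        assert list(out["project_geometries_invalid"]) == [True, False]
        assert out["nested_in"][1] == [] and out["intersecting_with"][1] == []

    def test_spatial_index_equals_brute_force_on_random_sites(self, frame):
        rng = np.random.default_rng(11)
        geoms = []
        for _ in range(200):
            cx, cy = rng.uniform(-8000, 8000, 2)
            w, h = rng.uniform(200, 1500, 2)
            geoms.append(Polygon([(cx, cy), (cx + w, cy), (cx + w, cy + h), (cx, cy + h)]))
        table = _table(frame, geoms)
        fast = classify_overlaps(table)
        slow = classify_overlaps(table, brute_force=True)
        pd.testing.assert_frame_equal(fast, slow)

    def test_relation_algebra(self, frame):
        """Mutual-containment symmetry and inverse relations across the table."""
        rng = np.random.default_rng(5)
        geoms = []
        for _ in range(60):
            cx, cy = rng.uniform(-4000, 4000, 2)
            w = rng.uniform(200, 2000)
            geoms.append(Polygon([(cx, cy), (cx + w, cy), (cx + w, cy + w), (cx, cy + w)]))
        out = classify_overlaps(_table(frame, geoms)).set_index("site_id")
        for sid, row in out.iterrows():
            assert sid not in row["nested_in"] + row["intersecting_with"]
            for other in row["nested_in"]:
                assert sid in out.loc[other, "contains_small_polygon"]
            for other in row["intersecting_with"]:
                assert sid in out.loc[other, "intersecting_with"]


class TestAnnulus:
    def test_disc_annulus_area_closed_form(self, cfg):
        disc = buffer_metric(Point(36.8, -1.3), 1000.0)
        ring = make_annulus(disc, cfg)
        assert geodesic_area_km2(ring) == pytest.approx(math.pi * (1.5**2 - 1.0**2), rel=0.01)

    def test_annulus_disjoint_from_site(self, unit_square_km, cfg):
        ring = make_annulus(unit_square_km, cfg)
        assert ring.intersection(unit_square_km).area == pytest.approx(0.0, abs=1e-12)

    def test_point_derived_disc_annulus(self, cfg):
        disc = buffer_metric(Point(36.8, -1.3), cfg.point_buffer_m)
        ring = make_annulus(disc, cfg)
        assert geodesic_area_km2(ring) == pytest.approx(math.pi * (0.6**2 - 0.1**2), rel=0.01)


def test_compute_flags_judges_validity_on_reported_geometry(frame, cfg):
    from ldis.sites_io import derive_geometry, harmonize_sites

    df = harmonize_sites(pd.DataFrame({
        "site_id": ["pt", "bad"],
        "geometry_reported": [
            Point(36.8, -1.3),
            frame.to_wgs84(Polygon([(0, 0), (1000, 1000), (1000, 0), (0, 1000)])),
        ],
    }))
    df = derive_geometry(df, cfg)
    flags = compute_flags(df, None, cfg)
    assert list(flags["project_geometries_invalid"]) == [False, True]
    assert bool(flags["is_perfectly_circular"][0])  # the 100 m disc
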