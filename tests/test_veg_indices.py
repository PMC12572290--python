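"""Spectral indices, cloud filtering, compositing and panel assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ldis import PipelineConfig
from ldis.raster import Raster
from ldis.veg_indices import (
    Scene,
    build_panel,
    cloud_fraction,
    greenest_months,
    ndre,
    ndvi,
    savi,
)


class TestIndexFormulas:
    def test_ndvi_arithmetic(self):
        assert ndvi(0.6, 0.2) == pytest.approx(0.5)
        assert ndvi(0.3, 0.3) == 0.0
        assert ndvi(0.2, 0.6) == pytest.approx(-ndvi(0.6, 0.2))
        assert np.isnan(ndvi(0.0, 0.0))

    def test_ndre_arithmetic(self):
        assert ndre(0.6, 0.3) == pytest.approx(1 / 3)
        assert ndre(0.5, 0.5) == 0.0
        assert ndre(1.0, 0.0) == 1.0

    def test_savi_default_red_edge_form(self):
        # (0.6-0.2)/(0.6+0.2+0.5) * 1.5
        assert savi(0.6, 0.2) == pytest.approx(0.4 / 1.3 * 1.5)
        assert savi(0.4, 0.4) == 0.0

    def test_savi_red_variant_same_formula_on_red(self):
        assert savi(0.6, 0.2) == pytest.approx(savi(0.6, 0.2))  # symmetric in band choice

    @given(nir=st.floats(0, 1), other=st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_normalised_indices_bounded(self, nir, other):
        for f in (ndvi, ndre):
            v = f(nir, other)
            if not np.isnan(v):
                assert -1.0 <= v <= 1.0

    def test_vectorised_over_arrays(self):
        n = np.array([0.6, 0.3, 0.0])
        r = np.array([0.2, 0.3, 0.0])
        out = ndvi(n, r)
        np.testing.assert_allclose(out[:2], [0.5, 0.0])
        assert np.isnan(out[2])


def _scene(vals, frame, cloud=None, month=None, year=2018):
    grid = Raster(np.zeros_like(vals, dtype=float),
                  x0=float(frame.inverse_lonlat(np.array(-1000.0), np.array(1000.0))[0]),
                  y0=float(frame.inverse_lonlat(np.array(-1000.0), np.array(1000.0))[1]),
                  dx=10 / 111_132.954, dy=10 / 111_132.954)
    nir = (1.0 + vals) / 2.0
    return Scene(year=year, month=month, nir=nir, red=1.0 - nir,
                 red_edge=(1.0 - nir).copy(), cloud=cloud, grid=grid)


class TestCloudFraction:
    def test_all_clear_retained_all_cloudy_rejected(self, frame, unit_square_km, cfg):
        vals = np.full((200, 200), 0.4)
        clear = _scene(vals, frame, cloud=np.zeros((200, 200), dtype=np.uint8))
        assert cloud_fraction(clear, unit_square_km) == 0.0
        cloudy = _scene(vals, frame, cloud=np.ones((200, 200), dtype=np.uint8))
        assert cloud_fraction(cloudy, unit_square_km) == 1.0

    def test_twenty_percent_boundary_is_strict(self, frame, metric_polygon, cfg):
        """Cloudy share just below 20% keeps a scene, at/above drops it."""
        from ldis.raster import zonal_cells

        site = metric_polygon([(-50, -50), (50, -50), (50, 50), (-50, 50)])
        grid = _scene(np.zeros((200, 200)), frame).grid
        cells = zonal_cells(grid, site)
        order = np.argsort(-cells.weights)
        total = cells.weights.sum()
        for target, keep in [(0.185, True), (0.205, False)]:
            mask = np.zeros((200, 200), dtype=np.uint8)
            cum = 0.0
            for idx in order:
                if cum / total >= target:
                    break
                mask[cells.rows[idx], cells.cols[idx]] = 1
                cum += cells.weights[idx]
            sc = _scene(np.full((200, 200), 0.4), frame, cloud=mask)
            frac = cloud_fraction(sc, site)
            # oracle: the painted weight share itself
            assert frac == pytest.approx(cum / total, abs=1e-9)
            assert (frac < cfg.cloud_frac_max) is keep, (target, frac)

    def test_no_mask_retained_with_warning(self, frame, unit_square_km, caplog):
        sc = _scene(np.full((200, 200), 0.4), frame, cloud=None)
        import logging

        with caplog.at_level(logging.WARNING):
            assert cloud_fraction(sc, unit_square_km) == 0.0
        assert any("no cloud mask" in r.message for r in caplog.records)


class TestGreenestMonths:
    def test_increasing_series_picks_last_three(self):
        assert greenest_months(np.linspace(0.1, 0.9, 12), k=3) == [10, 11, 12]

    def test_constant_series_tie_breaks_to_earliest(self):
        assert greenest_months(np.full(12, 0.5), k=3) == [1, 2, 3]

    def test_fixed_region_override(self):
        months = greenest_months(np.linspace(0.1, 0.9, 12), k=3,
                                 fixed_months=[1, 4, 5])
        assert months == [1, 4, 5]

    def test_fewer_than_k_available(self, caplog):
        vals = np.full(12, np.nan)
        vals[3] = 0.4
        vals[7] = 0.6
        import logging

        with caplog.at_level(logging.WARNING):
            assert greenest_months(vals, k=3) == [4, 8]


class TestBuildPanel:
    def test_uniform_raster_same_value_both_zones(self, frame, site_table, cfg):
        sc = _scene(np.full((400, 400), 0.4), frame,
                    cloud=np.zeros((400, 400), dtype=np.uint8))
        panel = build_panel(site_table, {"at_planting": [sc]}, cfg)
        assert set(panel["zone"]) == {"site", "annulus"}
        np.testing.assert_allclose(panel["ndvi"], 0.4, atol=1e-9)

    def test_zone_separation_no_leakage(self, frame, metric_polygon, cfg):
        """0.6 painted on cells inside the site, 0.2 outside: the site mean
        must be exactly 0.6 and the annulus mean must stay near 0.2."""
        from ldis.raster import zonal_cells
        from ldis.sites_io import derive_geometry, harmonize_sites

        site_geom = metric_polygon([(-200, -200), (200, -200), (200, 200), (-200, 200)])
        sites = derive_geometry(harmonize_sites(pd.DataFrame({
            "site_id": ["z"], "geometry_reported": [site_geom],
            "planting_date_reported": ["2018"],
        })), cfg)
        vals = np.full((400, 400), 0.2)
        grid = _scene(vals, frame).grid
        cells = zonal_cells(grid, site_geom)
        vals[cells.rows, cells.cols] = 0.6
        sc = _scene(vals, frame, cloud=np.zeros((400, 400), dtype=np.uint8))
        panel = build_panel(sites, {"at_planting": [sc]}, cfg).set_index("zone")
        assert panel.loc["site", "ndvi"] == pytest.approx(0.6, abs=1e-9)
        assert panel.loc["annulus", "ndvi"] == pytest.approx(0.2, abs=0.02)

    def test_period_years_follow_planting_date(self, frame, site_table, cfg):
        sc = {p: [_scene(np.full((400, 400), 0.4), frame,
                         cloud=np.zeros((400, 400), dtype=np.uint8))]
              for p in ("minus1", "at_planting", "plus5")}
        panel = build_panel(site_table, sc, cfg)
        years = panel.drop_duplicates("period").set_index("period")["year"]
        assert years["minus1"] == 2017 and years["at_planting"] == 2018
        assert years["plus5"] == 2023

    def test_site_without_planting_year_yields_no_rows(self, frame, cfg, unit_square_km):
        from ldis.sites_io import derive_geometry, harmonize_sites

        sites = derive_geometry(harmonize_sites(pd.DataFrame({
            "site_id": ["x"], "geometry_reported": [unit_square_km],
        })), cfg)
        sc = _scene(np.full((400, 400), 0.4), frame,
                    cloud=np.zeros((400, 400), dtype=np.uint8))
        panel = build_panel(sites, {"at_planting": [sc]}, cfg)
        assert panel.empty

    def test_greenest_month_composite_median(self, frame, site_table, cfg):
        """12 monthly scenes with increasing NDVI: composite = median of the
        top-3 months' zonal means."""
        monthly = [
            _scene(np.full((400, 400), 0.1 + 0.05 * m), frame, month=m,
                   cloud=np.zeros((400, 400), dtype=np.uint8))
            for m in range(1, 13)
        ]
        panel = build_panel(site_table, {"at_planting": monthly}, cfg)
        site_val = panel.set_index("zone").loc["site", "ndvi"]
        assert site_val == pytest.approx(0.1 + 0.05 * 11, abs=1e-9)  # median of months 10,11,12
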