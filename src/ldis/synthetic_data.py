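"""Seeded synthetic inputs emulating everything the pipeline consumes.

The generators fabricate site tables with the pathologies real registries
exhibit (point-only locations, near-perfect circles, administrative-area
copies, duplicates, nested children), secondary rasters whose true class
fractions are known to the generator within one cell of quantisation,
reflectance stacks whose painted NDVI trajectories follow the observed
narrative (pre-planting clearing dip, post-planting recovery, partial
spillover into the surrounding ring), and balanced 2x2 DiD panels with
named presets matching the published regression columns.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from shapely.geometry import Point, Polygon, LineString, box

from ._geodesy import LocalMetricFrame, geodesic_area_km2
from .config import PipelineConfig
from .geometry_integrity import compute_circularity, make_annulus
from .raster import Raster, zonal_cells
from .veg_indices import PERIODS, Scene

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiDParams:
    """Coefficients of the two-period model plus noise level and panel size."""

    intercept: float
    beta_g: float
    beta_t: float
    beta_gt: float
    residual_sd: float
    n_obs: int

    def cell_means(self) -> dict[str, float]:
        return {
            "control_before": self.intercept,
            "treat_before": self.intercept + self.beta_g,
            "control_after": self.intercept + self.beta_t,
            "treat_after": self.intercept + self.beta_g + self.beta_t + self.beta_gt,
        }

    def expected_r2(self) -> float:
        """Closed form var(cell means) / (var + sigma^2) for the balanced design."""
        m = np.array(list(self.cell_means().values()))
        v = m.var()
        return float(v / (v + self.residual_sd**2))


#: published regression columns as generator presets, keyed by comparison
#: period (the one-year-before preset prints n = 139,250; 139,248 is the
#: nearest size divisible into four equal cells)
DID_PRESETS: dict[str, DiDParams] = {
    "one_year_before": DiDParams(0.290, -0.105, 0.038, 0.038, 0.208, 139_248),
    "one_year_after": DiDParams(0.265, -0.090, 0.048, 0.048, 0.170, 469_500),
    "two_years_after": DiDParams(0.265, -0.090, 0.068, 0.059, 0.181, 469_500),
    "five_years_after": DiDParams(0.265, -0.090, 0.091, 0.074, 0.184, 469_500),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for a synthetic cohort.

    Geometry mix fractions refer to the reported geometries; extra
    duplicate / nested sites are injected on top of ``n_sites``.  NDVI
    trajectory defaults follow the observed narrative: sites are cleared at
    planting (dip), recover linearly, and partially leak greenness into
    their ring.
    """

    rng_seed: int = 0
    n_sites: int = 50
    frac_points: float = 0.2
    frac_circles: float = 0.1
    frac_admin_copies: float = 0.1
    dup_rate: float = 0.1
    nest_rate: float = 0.1
    raster_resolution_m: float = 30.0
    site_area_km2: float = 0.25
    centre_lon: float = 36.8
    centre_lat: float = -1.3
    planting_year: int = 2018
    # overlay ground-truth conditions: share of sites failing each rule and
    # the painted fraction when they do (clearly past the 10% / 20% rules)
    frac_sites_with_built: float = 0.2
    built_fraction: float = 0.30
    frac_sites_with_roads: float = 0.2
    road_cover_fraction: float = 0.20
    frac_sites_with_treecover: float = 0.2
    treecover_fraction: float = 0.40
    frac_sites_with_cropland: float = 0.2
    cropland_fraction: float = 0.40
    loss_pre1_fraction: float = 0.40
    # NDVI trajectory
    site_pre_ndvi: float = 0.29
    annulus_ndvi: float = 0.33
    background_ndvi: float = 0.20
    clearing_dip: float = 0.10
    growth_rate: float = 0.02
    spillover: float = 0.3
    did_params: dict = field(default_factory=lambda: dict(DID_PRESETS))

    def __post_init__(self) -> None:
        fracs = (self.frac_points, self.frac_circles, self.frac_admin_copies,
                 self.dup_rate, self.nest_rate)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("mix fractions must lie in [0, 1]")
        if self.frac_points + self.frac_circles + self.frac_admin_copies > 1.0:
            raise ValueError("geometry mix fractions exceed 1")


# -- site generation ----------------------------------------------------------

def _convex_site(frame: LocalMetricFrame, cx: float, cy: float, radius_m: float,
                 rng: np.random.Generator) -> Polygon:
    """Random convex polygon, squashed so it is never near-circular."""
    for squash in (0.55, 0.45, 0.35):
        pts = rng.uniform(-radius_m, radius_m, size=(9, 2))
        pts[:, 0] *= squash
        hull = shapely.convex_hull(shapely.multipoints(pts + [cx, cy]))
        geom = frame.to_wgs84(hull)
        if hull.geom_type == "Polygon" and compute_circularity(geom) < 0.90:
            return geom
    raise RuntimeError("could not generate a non-circular convex site")  # pragma: no cover


def gen_sites(cfg: ScenarioConfig, pipeline_cfg: PipelineConfig | None = None):
    """Generate (sites, admins, truth).

    ``truth`` records, per site, which geometry flags the integrity stage
    must raise: perfect-circle, admin-copy, nesting / duplicate /
    intersection relations (duplicates appear as mutual nesting, matching
    the relation convention downstream).
    """
    pipe = pipeline_cfg or PipelineConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    frame = LocalMetricFrame(cfg.centre_lon, cfg.centre_lat)
    radius_m = math.sqrt(cfg.site_area_km2 * 1e6 / math.pi)
    slot_m = max(4 * radius_m, 2 * radius_m + 2 * pipe.annulus_width_m + 500.0)
    n = cfg.n_sites
    n_pts = int(round(cfg.frac_points * n))
    n_circ = int(round(cfg.frac_circles * n))
    n_admin = int(round(cfg.frac_admin_copies * n))
    kinds = (["point"] * n_pts + ["circle"] * n_circ + ["admin"] * n_admin
             + ["polygon"] * (n - n_pts - n_circ - n_admin))
    rng.shuffle(kinds)

    # admin regions: a few rectangles in their own slots
    n_admin_regions = max(3, n_admin)
    admins_rows = []
    grid_cols = int(math.ceil(math.sqrt(n + n_admin_regions)))

    def slot_centre(i: int) -> tuple[float, float]:
        r, c = divmod(i, grid_cols)
        return (c - grid_cols / 2) * slot_m, (r - grid_cols / 2) * slot_m

    for a in range(n_admin_regions):
        cx, cy = slot_centre(n + a)
        w, h = radius_m * rng.uniform(1.2, 2.0), radius_m * rng.uniform(0.8, 1.4)
        admins_rows.append({
            "admin_id": f"adm{a}",
            "name": f"district {a}",
            "level": 2,
            "geometry": frame.to_wgs84(box(cx - w, cy - h, cx + w, cy + h)),
        })
    admins = pd.DataFrame(admins_rows)

    rows, truth_rows = [], []

    def add_site(sid: str, geom, *, perfect_circle: bool, admin_copy: bool,
                 nested_in=(), contains=(), intersecting=()):
        rows.append({
            "site_id": sid,
            "project_id_reported": f"proj{len(rows) % 7}",
            "host_name": "synthetic-registry",
            "url": "https://example.invalid/synthetic",
            "iso3": "KEN",
            "geometry_reported": geom,
            "planting_date_reported": f"{cfg.planting_year}",
            "planting_date_type": "planting",
        })
        truth_rows.append({
            "site_id": sid,
            "is_perfectly_circular": perfect_circle,
            "is_exact_administrative_area": admin_copy,
            "nested_in": sorted(nested_in),
            "contains_small_polygon": sorted(contains),
            "intersecting_with": sorted(intersecting),
        })

    admin_cursor = 0
    polygon_ids: list[str] = []
    for i, kind in enumerate(kinds):
        cx, cy = slot_centre(i)
        sid = f"s{i:04d}"
        if kind == "point":
            lon, lat = frame.inverse_lonlat(np.array(cx), np.array(cy))
            # the 100 m point buffer is a disc, so the circle flag must fire
            add_site(sid, Point(float(lon), float(lat)),
                     perfect_circle=True, admin_copy=False)
        elif kind == "circle":
            disc = shapely.Point(cx, cy).buffer(radius_m, quad_segs=64)
            add_site(sid, frame.to_wgs84(disc), perfect_circle=True, admin_copy=False)
        elif kind == "admin":
            region = admins.iloc[admin_cursor % len(admins)]
            admin_cursor += 1
            add_site(sid, region["geometry"], perfect_circle=False, admin_copy=True)
        else:
            geom = _convex_site(frame, cx, cy, radius_m, rng)
            add_site(sid, geom, perfect_circle=False, admin_copy=False)
            polygon_ids.append(sid)

    # inject duplicates and nested children on top of plain polygon sites
    by_id = {r["site_id"]: r for r in rows}
    truth_by_id = {t["site_id"]: t for t in truth_rows}
    n_dup = int(round(cfg.dup_rate * len(polygon_ids)))
    n_nest = int(round(cfg.nest_rate * len(polygon_ids)))
    hosts = list(rng.permutation(polygon_ids))
    dup_hosts, nest_hosts = hosts[:n_dup], hosts[n_dup:n_dup + n_nest]

    def scaled_copy(geom, factor: float):
        c = geom.centroid
        return shapely.affinity.scale(geom, xfact=factor, yfact=factor, origin=c)

    for j, host in enumerate(dup_hosts):
        sid = f"dup{j:03d}"
        # 99% concentric copy: mutual overlap > 95% both ways -> duplicate
        add_site(sid, scaled_copy(by_id[host]["geometry_reported"], 0.99),
                 perfect_circle=False, admin_copy=False,
                 nested_in=[host], contains=[host])
        truth_by_id[host]["nested_in"].append(sid)
        truth_by_id[host]["contains_small_polygon"].append(sid)
    for j, host in enumerate(nest_hosts):
        sid = f"nest{j:03d}"
        # half-linear-scale child: covers 25% of the parent, fully inside
        add_site(sid, scaled_copy(by_id[host]["geometry_reported"], 0.5),
                 perfect_circle=False, admin_copy=False, nested_in=[host])
        truth_by_id[host]["contains_small_polygon"].append(sid)

    for t in truth_rows:
        t["nested_in"] = sorted(t["nested_in"])
        t["contains_small_polygon"] = sorted(t["contains_small_polygon"])
        t["intersecting_with"] = sorted(t["intersecting_with"])

    from .sites_io import derive_geometry, harmonize_sites

    sites = derive_geometry(harmonize_sites(pd.DataFrame(rows)), pipe)
    return sites, admins, pd.DataFrame(truth_rows)


# -- raster generation --------------------------------------------------------

def _paint_fraction(raster_data: np.ndarray, raster: Raster, geom, value,
                    target_fraction: float) -> float:
    """Set cells inside ``geom`` to ``value`` until ~target share of the
    site area is covered; returns the achieved fraction."""
    cells = zonal_cells(raster, geom)
    if len(cells) == 0 or target_fraction <= 0:
        return 0.0
    order = np.argsort(-cells.weights)
    total = cells.weights.sum()
    cum = 0.0
    for idx in order:
        if cum / total >= target_fraction:
            break
        r, c = cells.rows[idx], cells.cols[idx]
        if raster_data[r, c] != 0:  # cell already claimed by another class
            continue
        raster_data[r, c] = value
        cum += cells.weights[idx]
    return cum / total


def _scenario_grid(sites: pd.DataFrame, cfg: ScenarioConfig, margin_m: float = 700.0):
    bounds = shapely.total_bounds(
        shapely.union_all([shapely.envelope(g) for g in sites["geometry_derived"]])
    )
    deg = cfg.raster_resolution_m / 111_132.954
    margin = margin_m / 111_132.954
    x0, y1 = bounds[0] - margin, bounds[3] + margin
    cols = int(math.ceil((bounds[2] + margin - x0) / deg))
    rows = int(math.ceil((y1 - (bounds[1] - margin)) / deg))
    return x0, y1, deg, rows, cols


def gen_rasters(cfg: ScenarioConfig, sites: pd.DataFrame,
                geometry_truth: pd.DataFrame | None = None):
    """Generate (layers, truth) for the overlay stage.

    layers: dict with ``built``, ``landcover``, ``lossyear``, ``dem``
    rasters and a ``roads`` GeoDataFrame-like table.  Land-cover codes:
    1 = tree cover, 2 = other vegetation, 3 = stable cropland,
    0 = background (counted in no class-set).  truth: per-site achieved
    fractions (within one cell of the configured targets).

    Sites that share area with another site (the relation labels from
    :func:`gen_sites`, if passed) are left unpainted so every painted cell
    belongs to exactly one site and the per-site target fractions stay
    exact.
    """
    rng = np.random.default_rng(cfg.rng_seed + 1)
    related: set[str] = set()
    if geometry_truth is not None:
        for _, t in geometry_truth.iterrows():
            if t["nested_in"] or t["contains_small_polygon"] or t["intersecting_with"]:
                related.add(t["site_id"])
    x0, y1, deg, rows, cols = _scenario_grid(sites, cfg)
    if cfg.raster_resolution_m**2 > cfg.site_area_km2 * 1e6:
        small = sites["site_id"].tolist()
        log.warning("raster resolution coarser than smallest site: %s", small[:5])
    built = np.zeros((rows, cols), dtype=np.uint8)
    landcover = np.zeros((rows, cols), dtype=np.uint8)
    lossyear = np.zeros((rows, cols), dtype=np.int16)
    dem = 500.0 + 0.05 * np.arange(cols)[None, :] * np.ones((rows, 1))
    grid = dict(x0=x0, y0=y1, dx=deg, dy=deg)
    built_r = Raster(built, **grid)
    land_r = Raster(landcover, **grid)
    loss_r = Raster(lossyear, **grid)
    dem_r = Raster(dem, **grid)

    paintable = np.array([
        i for i, sid in enumerate(sites["site_id"]) if sid not in related
    ])
    pick = lambda frac: set(
        paintable[rng.permutation(len(paintable))[: int(round(frac * len(paintable)))]]
    )
    with_built = pick(cfg.frac_sites_with_built)
    with_roads = pick(cfg.frac_sites_with_roads)
    with_tree = pick(cfg.frac_sites_with_treecover)
    with_crop = pick(cfg.frac_sites_with_cropland)

    roads_rows, truth_rows = [], []
    frame = LocalMetricFrame(cfg.centre_lon, cfg.centre_lat)
    for i, (_, site) in enumerate(sites.iterrows()):
        geom = site["geometry_derived"]
        unpainted = site["site_id"] in related
        t = {"site_id": site["site_id"]}
        t["built_fraction"] = (
            _paint_fraction(built, built_r, geom, 1, cfg.built_fraction)
            if i in with_built else 0.0
        )
        t["treecover_fraction"] = (
            _paint_fraction(landcover, land_r, geom, 1, cfg.treecover_fraction)
            if i in with_tree else 0.0
        )
        t["cropland_fraction"] = (
            _paint_fraction(landcover, land_r, geom, 3, cfg.cropland_fraction)
            if i in with_crop else 0.0
        )
        t["loss_pre1_fraction"] = 0.0 if unpainted else _paint_fraction(
            lossyear, loss_r, geom, cfg.planting_year - 1, cfg.loss_pre1_fraction
        )
        if i in with_roads:
            # parallel chords across the site at a spacing chosen to hit the
            # target corridor coverage: cover ~ corridor_width / spacing
            m = frame.to_metric(geom)
            minx, miny, maxx, maxy = m.bounds
            spacing = PipelineConfig().road_corridor_width_m / cfg.road_cover_fraction
            y = miny + spacing / 2
            while y < maxy:
                roads_rows.append({
                    "road_id": f"r{len(roads_rows)}",
                    "geometry": frame.to_wgs84(
                        LineString([(minx - 200, y), (maxx + 200, y)])
                    ),
                })
                y += spacing
            t["has_roads"] = True
        else:
            t["has_roads"] = False
        truth_rows.append(t)
    layers = {
        "built": built_r,
        "landcover": land_r,
        "lossyear": loss_r,
        "dem": dem_r,
        "roads": pd.DataFrame(roads_rows, columns=["road_id", "geometry"]),
    }
    return layers, pd.DataFrame(truth_rows)


#: class-code sets matching :func:`gen_rasters`
LANDCOVER_CLASSES = {
    "treecover_at_planting": {1},
    "other_landcover": {2},
    "stable_cropland": {3},
    "permanent_water": {4},
}


# -- reflectance generation ---------------------------------------------------

def site_ndvi_trajectory(cfg: ScenarioConfig) -> dict[str, float]:
    """Painted site NDVI per period: pre level, clearing dip, linear recovery."""
    at = cfg.site_pre_ndvi - cfg.clearing_dip
    return {
        "minus1": cfg.site_pre_ndvi,
        "at_planting": at,
        "plus1": at + cfg.growth_rate,
        "plus2": at + 2 * cfg.growth_rate,
        "plus5": at + 5 * cfg.growth_rate,
    }


def annulus_ndvi_trajectory(cfg: ScenarioConfig) -> dict[str, float]:
    """Ring NDVI: own baseline plus ``spillover`` x the site trend."""
    site = site_ndvi_trajectory(cfg)
    return {
        p: cfg.annulus_ndvi + cfg.spillover * (site[p] - site["minus1"])
        for p in site
    }


def _ndvi_to_bands(v: np.ndarray):
    """Invert NDVI with nir + red = 1, so ndvi(nir, red) = v exactly."""
    nir = (1.0 + v) / 2.0
    return nir, 1.0 - nir


def gen_reflectance(cfg: ScenarioConfig, sites: pd.DataFrame,
                    pipeline_cfg: PipelineConfig | None = None):
    """Per-period single-scene reflectance stacks painted from the NDVI
    trajectories; red-edge mirrors red so NDRE equals NDVI by construction."""
    pipe = pipeline_cfg or PipelineConfig()
    x0, y1, deg, rows, cols = _scenario_grid(sites, cfg)
    grid = Raster(np.zeros((rows, cols)), x0=x0, y0=y1, dx=deg, dy=deg)
    site_tr = site_ndvi_trajectory(cfg)
    ann_tr = annulus_ndvi_trajectory(cfg)
    scenes: dict[str, list[Scene]] = {}
    for period, offset in PERIODS.items():
        v = np.full((rows, cols), cfg.background_ndvi)
        # paint annuli first, then sites, so boundary cells belong to sites
        for _, site in sites.iterrows():
            ring = make_annulus(site["geometry_derived"], pipe)
            cells = zonal_cells(grid, ring)
            v[cells.rows, cells.cols] = ann_tr[period]
        for _, site in sites.iterrows():
            cells = zonal_cells(grid, site["geometry_derived"])
            v[cells.rows, cells.cols] = site_tr[period]
        nir, red = _ndvi_to_bands(v)
        scenes[period] = [Scene(
            year=cfg.planting_year + offset, month=None,
            nir=nir, red=red, red_edge=red.copy(),
            cloud=np.zeros((rows, cols), dtype=np.uint8), grid=grid,
        )]
    return scenes


# -- DiD panel generation -----------------------------------------------------

def gen_did_panel(
    params: DiDParams | str,
    n_obs: int | None = None,
    seed: int = 0,
    period_after: str = "plus1",
) -> pd.DataFrame:
    """Balanced 2x2 panel drawn from the two-period model.

    ``params`` is a :class:`DiDParams` or a preset name from
    :data:`DID_PRESETS`.  n_obs must be divisible by 4 (one observation per
    site x zone x period cell); noise is iid Gaussian.
    """
    if isinstance(params, str):
        params = DID_PRESETS[params]
    n_obs = int(n_obs if n_obs is not None else params.n_obs)
    if n_obs % 4:
        raise ValueError(f"n_obs must be divisible by 4, got {n_obs}")
    n_sites = n_obs // 4
    rng = np.random.default_rng(seed)
    means = params.cell_means()
    frames = []
    for zone, g in (("annulus", 0), ("site", 1)):
        for period, t in (("at_planting", 0), (period_after, 1)):
            key = ("control" if g == 0 else "treat") + ("_after" if t else "_before")
            frames.append(pd.DataFrame({
                "site_id": [f"p{i:06d}" for i in range(n_sites)],
                "zone": zone,
                "period": period,
                "year": 2018 + (PERIODS.get(period_after, 1) if t else 0),
                "ndvi": means[key] + rng.normal(0.0, params.residual_sd, n_sites),
                "ndre": np.nan,
                "savi": np.nan,
                "n_valid_cells": 1,
            }))
    return pd.concat(frames, ignore_index=True)


__all__ = [
    "DiDParams", "DID_PRESETS", "ScenarioConfig", "LANDCOVER_CLASSES",
    "gen_sites", "gen_rasters", "gen_reflectance", "gen_did_panel",
    "site_ndvi_trajectory", "annulus_ndvi_trajectory",
]
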