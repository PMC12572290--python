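"""Per-site overlays against secondary layers.

Everything here is a generic zonal computation on caller-supplied layers:
built-up share, road length / density / corridor coverage, land-cover class
shares (tree cover at planting, other land cover, stable cropland,
permanent water), loss-year window fractions around the planting year, and
terrain statistics.  The toolkit never fetches any of these layers itself.

Cells contribute their exact intersection area with the site polygon (not
centre-point membership) — the median site is far smaller than 1 km², where
centre-point rules quantise badly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from ._geodesy import LocalMetricFrame, geodesic_area_km2
from .config import PipelineConfig
from .raster import Raster, zonal_cells

log = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "site_id", "built_fraction", "road_length_km", "road_density_km_per_km2",
    "road_cover_fraction", "treecover_at_planting_fraction",
    "other_landcover_fraction", "stable_cropland_fraction",
    "permanent_water_fraction", "loss_frac_pre5", "loss_frac_pre1",
    "loss_frac_post5", "post5_truncated", "mean_elevation_m", "mean_slope_deg",
]


def class_fraction(
    geom: BaseGeometry, raster: Raster, classes: set[int] | frozenset[int],
    band: int | str = 0,
) -> tuple[float, float]:
    """(fraction of covered site area in ``classes``, coverage ratio).

    Fraction is NaN when the site misses the raster entirely; when coverage
    is partial the fraction refers to the covered part and the second return
    value says how much that is.
    """
    cells = zonal_cells(raster, geom)
    if len(cells) == 0 or cells.weights.sum() == 0:
        log.warning("site does not overlap raster extent")
        return float("nan"), 0.0
    if cells.coverage < 0.999:
        log.warning("site only %.1f%% covered by raster", 100 * cells.coverage)
    if not classes:
        return 0.0, cells.coverage
    vals = cells.values(np.asarray(raster.band(band)))
    in_class = np.isin(vals, list(classes))
    return float(cells.weights[in_class].sum() / cells.weights.sum()), cells.coverage


def road_metrics(
    geom: BaseGeometry, roads, cfg: PipelineConfig | None = None
) -> tuple[float, float, float]:
    """(road length km inside site, length per km², corridor-covered fraction).

    ``roads`` is any iterable of WGS84 line geometries (or a DataFrame with a
    ``geometry`` column).  Coverage buffers the clipped lines to the
    configured corridor width in the site's metric frame.
    """
    cfg = cfg or PipelineConfig()
    if hasattr(roads, "columns"):
        roads = list(roads["geometry"])
    area = geodesic_area_km2(geom)
    lines = [g.intersection(geom) for g in roads]
    lines = [g for g in lines if not g.is_empty]
    if not lines:
        return 0.0, 0.0, 0.0
    frame = LocalMetricFrame.around(geom)
    clipped_m = [frame.to_metric(g) for g in lines]
    length_km = sum(g.length for g in clipped_m) / 1e3
    corridor = shapely.unary_union(
        [g.buffer(cfg.road_corridor_width_m / 2.0, cap_style="flat") for g in clipped_m]
    )
    site_m = frame.to_metric(geom)
    cover = corridor.intersection(site_m).area / site_m.area if site_m.area else 0.0
    return length_km, (length_km / area if area else 0.0), cover


@dataclass
class LossWindows:
    pre5: float
    pre1: float
    post5: float
    post5_truncated: bool = False


def loss_window_fractions(
    geom: BaseGeometry, lossyear: Raster, planting_year: int | None,
    epoch: tuple[int, int] | None = None,
) -> LossWindows:
    """Site-area fractions with first loss in windows around planting.

    The loss raster encodes the first loss year per cell (0 = never lost).
    Windows: pre5 = [planting-5, planting-1], pre1 = {planting-1},
    post5 = [planting+1, planting+5] truncated at the raster's last covered
    year (``epoch``, default inferred from the data) with the truncation
    flagged; an empty post window yields NaN.
    """
    if planting_year is None:
        return LossWindows(float("nan"), float("nan"), float("nan"))
    cells = zonal_cells(lossyear, geom)
    if len(cells) == 0:
        return LossWindows(float("nan"), float("nan"), float("nan"))
    years = cells.values(np.asarray(lossyear.band(0)))
    w = cells.weights
    total = w.sum()

    def frac(lo: int, hi: int) -> float:
        mask = (years >= lo) & (years <= hi) & (years > 0)
        return float(w[mask].sum() / total)

    if epoch is None:
        observed = years[years > 0]
        last = int(observed.max()) if observed.size else planting_year + 5
    else:
        last = epoch[1]
    post_end = min(planting_year + 5, last)
    truncated = post_end < planting_year + 5
    if post_end < planting_year + 1:
        log.warning("post-planting loss window empty (planting in final raster year)")
        post5 = float("nan")
    else:
        post5 = frac(planting_year + 1, post_end)
    return LossWindows(
        pre5=frac(planting_year - 5, planting_year - 1),
        pre1=frac(planting_year - 1, planting_year - 1),
        post5=post5,
        post5_truncated=truncated,
    )


def terrain_stats(geom: BaseGeometry, dem: Raster) -> tuple[float, float]:
    """(mean elevation m, mean slope deg) over cells intersecting the site.

    Slope uses Horn's 3x3 finite differences on the DEM with the grid
    spacing resolved to metres at each row's latitude.
    """
    cells = zonal_cells(dem, geom)
    if len(cells) == 0:
        return float("nan"), float("nan")
    z = np.asarray(dem.band(0), dtype=float)
    mean_elev = float(np.average(cells.values(z), weights=cells.weights))
    slope = _horn_slope_deg(z, dem)
    mean_slope = float(np.average(slope[cells.rows, cells.cols], weights=cells.weights))
    return mean_elev, mean_slope


def _horn_slope_deg(z: np.ndarray, dem: Raster) -> np.ndarray:
    rows, cols = z.shape
    zp = np.pad(z, 1, mode="edge")
    # Horn kernel: weighted differences across the 3x3 neighbourhood
    dz_dx_num = (
        (zp[0:-2, 2:] + 2 * zp[1:-1, 2:] + zp[2:, 2:])
        - (zp[0:-2, 0:-2] + 2 * zp[1:-1, 0:-2] + zp[2:, 0:-2])
    )
    dz_dy_num = (
        (zp[2:, 0:-2] + 2 * zp[2:, 1:-1] + zp[2:, 2:])
        - (zp[0:-2, 0:-2] + 2 * zp[0:-2, 1:-1] + zp[0:-2, 2:])
    )
    lat_centres = dem.y0 - (np.arange(rows) + 0.5) * dem.dy
    m_per_deg_lat = 111_132.954
    dx_m = dem.dx * m_per_deg_lat * np.cos(np.radians(lat_centres))[:, None]
    dy_m = dem.dy * m_per_deg_lat
    dz_dx = dz_dx_num / (8.0 * dx_m)
    dz_dy = -dz_dy_num / (8.0 * dy_m)  # grid rows run north->south
    return np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))


def compute_metrics(
    sites: pd.DataFrame,
    *,
    built: Raster | None = None,
    built_classes: set[int] = frozenset({1}),
    landcover: Raster | None = None,
    landcover_classes: dict[str, set[int]] | None = None,
    lossyear: Raster | None = None,
    loss_epoch: tuple[int, int] | None = None,
    roads=None,
    dem: Raster | None = None,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Overlay every site against whichever layers are supplied.

    ``landcover_classes`` maps the metric names ``treecover_at_planting``,
    ``other_landcover``, ``stable_cropland``, ``permanent_water`` to sets of
    class codes in the land-cover raster.  Absent layers yield missing
    metrics (NaN), which the scoring stage treats as unevaluated.
    """
    cfg = cfg or PipelineConfig()
    landcover_classes = landcover_classes or {}
    rows = []
    for _, site in sites.iterrows():
        geom = site["geometry_derived"]
        rec: dict = {"site_id": site["site_id"]}
        nan = float("nan")
        rec["built_fraction"] = (
            class_fraction(geom, built, built_classes)[0] if built is not None else nan
        )
        if roads is not None:
            rec["road_length_km"], rec["road_density_km_per_km2"], rec["road_cover_fraction"] = (
                road_metrics(geom, roads, cfg)
            )
        else:
            rec["road_length_km"] = rec["road_density_km_per_km2"] = nan
            rec["road_cover_fraction"] = nan
        for name, key in [
            ("treecover_at_planting", "treecover_at_planting_fraction"),
            ("other_landcover", "other_landcover_fraction"),
            ("stable_cropland", "stable_cropland_fraction"),
            ("permanent_water", "permanent_water_fraction"),
        ]:
            if landcover is not None and name in landcover_classes:
                rec[key] = class_fraction(geom, landcover, landcover_classes[name])[0]
            else:
                rec[key] = nan
        year = site.get("planting_date_reported")
        planting_year = None if pd.isna(year) else int(pd.Timestamp(year).year)
        if lossyear is not None:
            lw = loss_window_fractions(geom, lossyear, planting_year, epoch=loss_epoch)
            rec.update(loss_frac_pre5=lw.pre5, loss_frac_pre1=lw.pre1,
                       loss_frac_post5=lw.post5, post5_truncated=lw.post5_truncated)
        else:
            rec.update(loss_frac_pre5=nan, loss_frac_pre1=nan,
                       loss_frac_post5=nan, post5_truncated=False)
        if dem is not None:
            rec["mean_elevation_m"], rec["mean_slope_deg"] = terrain_stats(geom, dem)
        else:
            rec["mean_elevation_m"] = rec["mean_slope_deg"] = nan
        rows.append(rec)
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


__all__ = [
    "METRIC_COLUMNS", "LossWindows", "class_fraction", "road_metrics",
    "loss_window_fractions", "terrain_stats", "compute_metrics",
]
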