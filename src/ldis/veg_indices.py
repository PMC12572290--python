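"""Vegetation indices, cloud filtering, compositing and index panels.

NDVI = (NIR − Red)/(NIR + Red) tracks presence of green vegetation;
NDRE swaps Red for the red-edge band and is sensitive to chlorophyll and
stress; SAVI adds a soil-brightness term L for sparse canopies.  The SAVI
default here uses the red-edge band with L = 0.5 and gain (1 + L) — the
variant this pipeline standardises on — with a config switch for the
textbook red-band form.

Annual values are composites over the top-k greenest months (ranked by
monthly zonal-mean NDVI) to suppress seasonality; scenes with too much
cloud over the zone footprint are dropped before compositing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry

from .config import PipelineConfig
from .geometry_integrity import make_annulus
from .raster import Raster, zonal_cells

log = logging.getLogger(__name__)

#: panel periods and their offsets from the planting year
PERIODS = {"minus1": -1, "at_planting": 0, "plus1": 1, "plus2": 2, "plus5": 5}
ZONES = ("site", "annulus")


def _safe_ratio(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den != 0, num / den, np.nan)
    return out if out.ndim else float(out)


def ndvi(nir, red):
    """(NIR − Red)/(NIR + Red); NaN where the denominator vanishes."""
    return _safe_ratio(np.subtract(nir, red), np.add(nir, red))


def ndre(nir, red_edge):
    """(NIR − RedEdge)/(NIR + RedEdge); NaN where the denominator vanishes."""
    return _safe_ratio(np.subtract(nir, red_edge), np.add(nir, red_edge))


def savi(nir, red_or_red_edge, soil_factor: float = 0.5, gain: float = 1.5):
    """Soil-adjusted index (NIR − band)/(NIR + band + L) · gain."""
    return np.multiply(
        _safe_ratio(
            np.subtract(nir, red_or_red_edge),
            np.add(np.add(nir, red_or_red_edge), soil_factor),
        ),
        gain,
    )


@dataclass
class Scene:
    """One reflectance acquisition on a common grid.

    Bands are 2-D arrays in surface-reflectance units [0, 1] (integer DN
    inputs should be divided by their scale factor first); ``cloud`` is a
    boolean/0-1 mask, 1 = cloudy, or None when no mask is available.
    """

    year: int
    month: int | None
    nir: np.ndarray
    red: np.ndarray
    red_edge: np.ndarray | None = None
    cloud: np.ndarray | None = None
    grid: Raster | None = None  # georeference; data ignored

    def raster_of(self, band: np.ndarray) -> Raster:
        g = self.grid
        return Raster(band, x0=g.x0, y0=g.y0, dx=g.dx, dy=g.dy)


def cloud_fraction(scene: Scene, geom: BaseGeometry) -> float:
    """Area-weighted cloudy share of the zone footprint; 0 if no mask."""
    if scene.cloud is None:
        log.warning("scene %s-%s has no cloud mask; retained", scene.year, scene.month)
        return 0.0
    cells = zonal_cells(scene.raster_of(scene.cloud), geom)
    if len(cells) == 0:
        return float("nan")
    cloudy = cells.values(np.asarray(scene.cloud)) > 0
    return float(cells.weights[cloudy].sum() / cells.weights.sum())


def greenest_months(
    monthly_ndvi, k: int = 3, fixed_months: list[int] | None = None
) -> list[int]:
    """Pick the k months (1-based) with highest NDVI; ties favour earlier
    months; a fixed regional month list bypasses selection entirely."""
    if fixed_months is not None:
        return list(fixed_months)
    vals = np.asarray(monthly_ndvi, dtype=float)
    if vals.shape != (12,):
        raise ValueError("expected 12 monthly NDVI values")
    ok = np.flatnonzero(np.isfinite(vals))
    if len(ok) < k:
        log.warning("only %d non-missing months available (k=%d)", len(ok), k)
    order = sorted(ok, key=lambda i: (-vals[i], i))
    return sorted(int(i) + 1 for i in order[:k])


def _zone_stats(scene: Scene, geom: BaseGeometry, cfg: PipelineConfig):
    """Per-scene index means over valid (non-cloud) cells of one zone."""
    cells = zonal_cells(scene.raster_of(scene.nir), geom)
    if len(cells) == 0:
        return None
    keep = np.ones(len(cells), dtype=bool)
    if scene.cloud is not None:
        keep &= cells.values(np.asarray(scene.cloud)) == 0
    if not keep.any():
        return None
    w = cells.weights[keep]
    nir = cells.values(np.asarray(scene.nir, dtype=float))[keep]
    red = cells.values(np.asarray(scene.red, dtype=float))[keep]
    re = (cells.values(np.asarray(scene.red_edge, dtype=float))[keep]
          if scene.red_edge is not None else None)

    def wmean(x):
        m = np.isfinite(x)
        return float(np.average(x[m], weights=w[m])) if m.any() else float("nan")

    savi_band = red if (cfg.savi_uses_red or re is None) else re
    return {
        "ndvi": wmean(ndvi(nir, red)),
        "ndre": wmean(ndre(nir, re)) if re is not None else float("nan"),
        "savi": wmean(savi(nir, savi_band, cfg.savi_soil_factor, cfg.savi_gain)),
        "n_valid_cells": int(keep.sum()),
    }


def build_panel(
    sites: pd.DataFrame,
    scenes: dict[str, list[Scene]],
    cfg: PipelineConfig | None = None,
    fixed_months: list[int] | None = None,
) -> pd.DataFrame:
    """Site/annulus index panel per period.

    ``scenes`` maps period names (keys of :data:`PERIODS`) to the candidate
    scenes of that period (typically monthly).  Per site x zone x period:
    cloud-heavy scenes (cloudy share >= ``cloud_frac_max`` over the zone)
    are dropped, the top-k greenest remaining months are composited
    (median by default), and the zonal means of each index are recorded.
    Rows are simply absent where nothing usable remains — balancing the
    panel is the analysis stage's job.
    """
    cfg = cfg or PipelineConfig()
    rows = []
    for _, site in sites.iterrows():
        if pd.isna(site.get("planting_date_reported")):
            log.info("site %s has no planting year; skipped", site["site_id"])
            continue
        planting_year = int(pd.Timestamp(site["planting_date_reported"]).year)
        geom = site["geometry_derived"]
        zones = {"site": geom, "annulus": make_annulus(geom, cfg)}
        for period, offset in PERIODS.items():
            candidates = scenes.get(period) or []
            if not candidates:
                continue
            for zone_name, zone_geom in zones.items():
                usable = [
                    s for s in candidates
                    if cloud_fraction(s, zone_geom) < cfg.cloud_frac_max
                ]
                if not usable:
                    continue
                stats = [(_zone_stats(s, zone_geom, cfg), s) for s in usable]
                stats = [(st, s) for st, s in stats if st is not None]
                if not stats:
                    continue
                if len(stats) > cfg.greenest_k:
                    if fixed_months is not None:
                        chosen = [
                            (st, s) for st, s in stats if s.month in fixed_months
                        ] or stats
                    else:
                        monthly = np.full(12, np.nan)
                        for st, s in stats:
                            if s.month is not None:
                                monthly[s.month - 1] = st["ndvi"]
                        months = greenest_months(monthly, cfg.greenest_k)
                        chosen = [(st, s) for st, s in stats if s.month in months] or stats
                else:
                    chosen = stats
                agg = np.median if cfg.composite_statistic == "median" else np.mean
                rows.append({
                    "site_id": site["site_id"],
                    "zone": zone_name,
                    "period": period,
                    "year": planting_year + offset,
                    "ndvi": float(agg([st["ndvi"] for st, _ in chosen])),
                    "ndre": float(agg([st["ndre"] for st, _ in chosen])),
                    "savi": float(agg([st["savi"] for st, _ in chosen])),
                    "n_valid_cells": int(np.mean([st["n_valid_cells"] for st, _ in chosen])),
                })
    return pd.DataFrame(
        rows, columns=["site_id", "zone", "period", "year", "ndvi", "ndre",
                       "savi", "n_valid_cells"],
    )


__all__ = [
    "PERIODS", "ZONES", "Scene", "ndvi", "ndre", "savi",
    "cloud_fraction", "greenest_months", "build_panel",
]
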