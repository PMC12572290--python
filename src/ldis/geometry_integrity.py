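"""Geometric integrity diagnostics for site polygons.

Covers the shape-based half of the integrity assessment: topological
validity, compactness ("circularity"), resemblance to administrative areas,
pairwise nesting / duplicate / intersection relations, and the outer annulus
used as spatial control.

Circularity is the Polsby–Popper isoperimetric quotient 4·pi·A / P²,
computed in a local metric frame — exactly 1 for a disc, pi/4 for a square.
Near-perfect circularity flags buffered point locations masquerading as
mapped planting areas.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from ._geodesy import buffer_metric, geodesic_area_km2, metric_perimeter_and_area
from .config import PipelineConfig

log = logging.getLogger(__name__)

FLAG_COLUMNS = [
    "site_id", "circularity", "is_perfectly_circular", "is_exact_administrative_area",
    "matched_admin_id", "project_geometries_invalid", "nested_in",
    "intersecting_with", "contains_small_polygon",
]


def validate_geometry(geom: BaseGeometry | None) -> bool:
    """True iff the geometry is a properly closed, simple, positive-area polygon."""
    if geom is None or geom.is_empty:
        return False
    if geom.geom_type not in ("Polygon", "MultiPolygon"):
        return False
    return bool(shapely.is_valid(geom)) and geom.area > 0


def compute_circularity(geom: BaseGeometry) -> float:
    """Polsby–Popper compactness 4·pi·A/P² in a metric frame; 1 for a disc."""
    if not validate_geometry(geom):
        raise ValueError("circularity requires a valid positive-area polygon")
    perimeter, area = metric_perimeter_and_area(geom)
    return 4.0 * math.pi * area / perimeter**2


def flag_perfect_circle(circularity: float, cfg: PipelineConfig) -> bool:
    return circularity >= cfg.circle_frac


def match_admin_area(
    geom: BaseGeometry, admins: pd.DataFrame, cfg: PipelineConfig
) -> tuple[bool, str | None]:
    """Does the site mutually overlap an administrative region above threshold?

    Both |geom ∩ admin| / |geom| and |geom ∩ admin| / |admin| must exceed
    ``cfg.admin_overlap_frac`` (strict).  Among several qualifying regions
    the one maximising the smaller of the two ratios wins.
    """
    if admins.empty:
        return False, None
    geom_area = geodesic_area_km2(geom)
    if geom_area == 0:
        return False, None
    tree = STRtree(list(admins["geometry"]))
    best: tuple[float, str] | None = None
    for idx in tree.query(geom, predicate="intersects"):
        admin_geom = admins["geometry"].iloc[idx]
        inter = geom.intersection(admin_geom)
        if inter.is_empty:
            continue
        inter_area = geodesic_area_km2(inter)
        r_geom = inter_area / geom_area
        admin_area = geodesic_area_km2(admin_geom)
        r_admin = inter_area / admin_area if admin_area else 0.0
        score = min(r_geom, r_admin)
        if r_geom > cfg.admin_overlap_frac and r_admin > cfg.admin_overlap_frac:
            if best is None or score > best[0]:
                best = (score, str(admins["admin_id"].iloc[idx]))
    return (True, best[1]) if best else (False, None)


def classify_overlaps(
    sites: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    *,
    geometry_column: str = "geometry_derived",
    brute_force: bool = False,
) -> pd.DataFrame:
    """Pairwise nesting / duplicate / intersection relations for a site table.

    For each intersecting pair (A, B) with overlap ratios rA = I/|A|,
    rB = I/|B| against the duplicate threshold t (strict ``>``):

    * rA > t and rB > t — duplicates, recorded as mutual nesting (the
      published schema has no separate duplicate relation) and logged;
    * rA > t only — A is nested in B, B contains A;
    * otherwise — plain mutual intersection.

    Candidate pairs come from an STRtree spatial index; ``brute_force=True``
    switches to all-pairs (the cross-check used in tests).
    Invalid geometries are skipped and flagged.
    """
    cfg = cfg or PipelineConfig()
    t = cfg.dup_overlap_frac
    ids = sites["site_id"].astype(str).tolist()
    geoms = list(sites[geometry_column])
    valid = [validate_geometry(g) for g in geoms]
    areas = [geodesic_area_km2(g) if v else 0.0 for g, v in zip(geoms, valid)]
    nested_in: list[list[str]] = [[] for _ in ids]
    contains: list[list[str]] = [[] for _ in ids]
    intersecting: list[list[str]] = [[] for _ in ids]

    if brute_force:
        pairs = [(i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    else:
        tree = STRtree([g for g, v in zip(geoms, valid) if v])
        valid_idx = [i for i, v in enumerate(valid) if v]
        raw = tree.query(tree.geometries, predicate="intersects")
        pairs = sorted(
            {(valid_idx[a], valid_idx[b]) for a, b in zip(*raw) if valid_idx[a] < valid_idx[b]}
        )
    n_dup = 0
    for i, j in pairs:
        if not (valid[i] and valid[j]):
            continue
        inter = geoms[i].intersection(geoms[j])
        if inter.is_empty:
            continue
        inter_area = geodesic_area_km2(inter)
        if inter_area == 0:
            continue
        ri, rj = inter_area / areas[i], inter_area / areas[j]
        if ri > t and rj > t:
            n_dup += 1
            nested_in[i].append(ids[j]); contains[i].append(ids[j])
            nested_in[j].append(ids[i]); contains[j].append(ids[i])
        elif ri > t:
            nested_in[i].append(ids[j]); contains[j].append(ids[i])
        elif rj > t:
            nested_in[j].append(ids[i]); contains[i].append(ids[j])
        else:
            intersecting[i].append(ids[j]); intersecting[j].append(ids[i])
    if n_dup:
        log.info("flagged %d near-duplicate site pairs (recorded as mutual nesting)", n_dup)
    return pd.DataFrame({
        "site_id": ids,
        "project_geometries_invalid": [not v for v in valid],
        "nested_in": [sorted(x) for x in nested_in],
        "intersecting_with": [sorted(x) for x in intersecting],
        "contains_small_polygon": [sorted(x) for x in contains],
    })


def make_annulus(geom: BaseGeometry, cfg: PipelineConfig | None = None) -> BaseGeometry:
    """Ring between the polygon boundary and its outward metric extension."""
    cfg = cfg or PipelineConfig()
    if not validate_geometry(geom):
        raise ValueError("annulus requires a valid polygon")
    return buffer_metric(geom, cfg.annulus_width_m).difference(geom)


def compute_flags(
    sites: pd.DataFrame,
    admins: pd.DataFrame | None = None,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Full per-site geometry diagnostics table (the flags half of the score)."""
    cfg = cfg or PipelineConfig()
    relations = classify_overlaps(sites, cfg)
    circ, perfect, is_admin, admin_ids = [], [], [], []
    for geom_rep, geom in zip(sites["geometry_reported"], sites["geometry_derived"]):
        if not validate_geometry(geom):
            circ.append(np.nan); perfect.append(False)
            is_admin.append(False); admin_ids.append(None)
            continue
        c = compute_circularity(geom)
        circ.append(c)
        perfect.append(flag_perfect_circle(c, cfg))
        if admins is not None and not admins.empty:
            ok, aid = match_admin_area(geom, admins, cfg)
        else:
            ok, aid = False, None
        is_admin.append(ok); admin_ids.append(aid)
    out = relations.copy()
    out.insert(1, "circularity", circ)
    out.insert(2, "is_perfectly_circular", perfect)
    out.insert(3, "is_exact_administrative_area", is_admin)
    out.insert(4, "matched_admin_id", admin_ids)
    # validity is judged on the *reported* geometry (points are valid inputs)
    out["project_geometries_invalid"] = [
        not (g.geom_type == "Point" or validate_geometry(g))
        for g in sites["geometry_reported"]
    ]
    return out[FLAG_COLUMNS]


__all__ = [
    "FLAG_COLUMNS", "validate_geometry", "compute_circularity", "flag_perfect_circle",
    "match_admin_area", "classify_overlaps", "make_annulus", "compute_flags",
]
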