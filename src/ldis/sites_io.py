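"""Reading, harmonising and writing planting-site tables.

A site table is a pandas DataFrame with shapely geometries in the
``geometry_reported`` / ``geometry_derived`` columns — the unit of analysis
is the *planting site*: a closed, contiguous area with non-zero area where
trees were reportedly planted.  Source tables are messy (duplicate ids,
multipolygons, point-only locations, areas in hectares), so the reader
harmonises rather than rejects: duplicate ids are deterministically
suffixed, multiparts are exploded into individual sites, and point
locations are replaced by a metric disc for all downstream area work.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as _shape, mapping as _mapping, Point

from ._geodesy import buffer_metric, geodesic_area_km2, validate_lonlat
from .config import PipelineConfig

log = logging.getLogger(__name__)

#: canonical metadata columns, in output order
SITE_COLUMNS = [
    "site_id", "project_id_reported", "host_name", "url", "iso3",
    "geometry_reported", "geometry_derived", "geometry_kind",
    "planting_date_reported", "planting_date_type",
    "area_reported_km2", "area_derived_km2",
]

PLANTING_DATE_TYPES = {
    "planting", "registration", "intervention_year", "crediting_start", "unknown",
}

#: source-column aliases folded into the canonical names
_RENAMES = {
    "site_id_reported": "site_id",
    "site_id_created": "site_id",
    "id": "site_id",
    "project_id": "project_id_reported",
    "host": "host_name",
    "country": "iso3",
    "planting_date": "planting_date_reported",
    "geometry": "geometry_reported",
    "wkt": "geometry_reported",
    "area_reported": "area_reported_km2",
}

_AREA_UNITS_TO_KM2 = {
    "km2": 1.0, "km^2": 1.0, "km²": 1.0, "sqkm": 1.0,
    "ha": 0.01, "hectare": 0.01, "hectares": 0.01,
    "m2": 1e-6, "m^2": 1e-6, "m²": 1e-6, "sqm": 1e-6,
    "acre": 0.00404686, "acres": 0.00404686,
}


def parse_area_km2(value, unit: str | None = None) -> float:
    """Normalise an area to km². Accepts numbers or strings like ``"250 ha"``."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    if isinstance(value, str):
        m = re.fullmatch(r"\s*([0-9.eE+-]+)\s*([a-zA-Z²^0-9]*)\s*", value)
        if not m:
            raise ValueError(f"cannot parse area {value!r}")
        value, parsed_unit = float(m.group(1)), m.group(2) or None
        unit = parsed_unit or unit
    factor = _AREA_UNITS_TO_KM2[unit.lower()] if unit else 1.0
    area = float(value) * factor
    if area < 0:
        raise ValueError(f"negative area: {value}")
    return area


def parse_planting_date(value) -> pd.Timestamp:
    """Parse a reported planting date; bare years resolve to July 1."""
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return pd.NaT
    if isinstance(value, (int, np.integer)) or (
        isinstance(value, str) and re.fullmatch(r"\d{4}", value.strip())
    ):
        year = int(value)
        log.debug("year-only planting date %s resolved to %s-07-01", value, year)
        return pd.Timestamp(year=year, month=7, day=1)
    if isinstance(value, float) and float(value).is_integer() and 1900 < value < 2200:
        return pd.Timestamp(year=int(value), month=7, day=1)
    return pd.to_datetime(value)


def _dedupe_ids(ids: pd.Series) -> pd.Series:
    seen: dict[str, int] = {}
    out = []
    n_dup = 0
    for raw in ids.astype(str):
        if raw in seen:
            seen[raw] += 1
            out.append(f"{raw}__{seen[raw]}")
            n_dup += 1
        else:
            seen[raw] = 1
            out.append(raw)
    if n_dup:
        log.warning("deduplicated %d repeated site_id values by suffixing", n_dup)
    return pd.Series(out, index=ids.index)


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = path.suffix.lower()
    return {".geojson": "geojson", ".json": "geojson", ".csv": "csv",
            ".parquet": "parquet"}.get(suffix, suffix.lstrip("."))


def read_sites(path, format: str | None = None) -> pd.DataFrame:
    """Read a site table from GeoJSON, CSV-with-WKT or (Geo)Parquet.

    Rows without a parseable geometry are excluded (counted in the log, not
    fatal); duplicate ids are suffixed; areas are normalised to km².
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    if fmt == "geojson":
        fc = json.loads(path.read_text())
        rows = []
        for feat in fc.get("features", []):
            props = dict(feat.get("properties") or {})
            geom = feat.get("geometry")
            props["geometry_reported"] = _shape(geom) if geom else None
            rows.append(props)
        df = pd.DataFrame(rows)
    elif fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "parquet":
        import pyarrow.parquet as pq

        df = pq.read_table(path).to_pandas()
    else:
        raise ValueError(f"unsupported site-table format: {fmt!r}")
    return harmonize_sites(df)


def harmonize_sites(df: pd.DataFrame) -> pd.DataFrame:
    """Align column names/units and enforce the site-table contract."""
    df = df.rename(columns={k: v for k, v in _RENAMES.items() if k in df.columns})
    if "geometry_reported" not in df.columns:
        raise ValueError("no geometry column found")
    geoms = []
    for g in df["geometry_reported"]:
        if isinstance(g, (bytes, bytearray)):
            g = shapely.from_wkb(bytes(g))
        elif isinstance(g, str):
            g = shapely.from_wkt(g) if g.strip() else None
        elif isinstance(g, float) and np.isnan(g):
            g = None
        geoms.append(None if g is None or g.is_empty else g)
    df = df.assign(geometry_reported=geoms)
    missing = df["geometry_reported"].isna()
    if missing.any():
        log.warning("excluded %d rows lacking a geometry", int(missing.sum()))
        df = df.loc[~missing].reset_index(drop=True)
    if "site_id" not in df.columns:
        df["site_id"] = [f"site{i}" for i in range(len(df))]
    df["site_id"] = _dedupe_ids(df["site_id"])
    unit_col = df["area_unit"] if "area_unit" in df.columns else [None] * len(df)
    if "area_reported_km2" in df.columns:
        df["area_reported_km2"] = [
            parse_area_km2(v, u) for v, u in zip(df["area_reported_km2"], unit_col)
        ]
    else:
        df["area_reported_km2"] = np.nan
    df["planting_date_reported"] = (
        [parse_planting_date(v) for v in df["planting_date_reported"]]
        if "planting_date_reported" in df.columns else pd.NaT
    )
    if "planting_date_type" not in df.columns:
        df["planting_date_type"] = "unknown"
    df["planting_date_type"] = df["planting_date_type"].fillna("unknown")
    bad_type = ~df["planting_date_type"].isin(PLANTING_DATE_TYPES)
    if bad_type.any():
        df.loc[bad_type, "planting_date_type"] = "unknown"
    df["geometry_kind"] = [
        "point" if g.geom_type == "Point" else "polygon" for g in df["geometry_reported"]
    ]
    for col in ("project_id_reported", "host_name", "url", "iso3"):
        if col not in df.columns:
            df[col] = None
    if "geometry_derived" in df.columns:
        df["geometry_derived"] = [
            shapely.from_wkb(bytes(g)) if isinstance(g, (bytes, bytearray))
            else shapely.from_wkt(g) if isinstance(g, str) else g
            for g in df["geometry_derived"]
        ]
    ordered = [c for c in SITE_COLUMNS if c in df.columns]
    extras = [c for c in df.columns if c not in SITE_COLUMNS and c != "area_unit"]
    return df[ordered + extras]


def explode_multipolygons(sites: pd.DataFrame) -> pd.DataFrame:
    """Split multipolygon sites into one record per part.

    Children are renamed ``<parent>#k`` in drawing order (1-based) with the
    parent id kept in ``parent_site_id``; zero-area sliver parts are dropped.
    """
    rows = []
    n_slivers = 0
    for _, row in sites.iterrows():
        geom = row["geometry_reported"]
        if geom.geom_type != "MultiPolygon":
            rows.append(row)
            continue
        k = 0
        for part in geom.geoms:
            if part.area == 0 or geodesic_area_km2(part) == 0:
                n_slivers += 1
                continue
            k += 1
            child = row.copy()
            child["site_id"] = f"{row['site_id']}#{k}"
            child["parent_site_id"] = row["site_id"]
            child["geometry_reported"] = part
            if "geometry_derived" in child.index:
                child["geometry_derived"] = part
            rows.append(child)
    if n_slivers:
        log.warning("dropped %d zero-area multipolygon parts", n_slivers)
    out = pd.DataFrame(rows).reset_index(drop=True)
    if "parent_site_id" in out.columns:
        out["parent_site_id"] = out["parent_site_id"].where(out["parent_site_id"].notna())
    return out


def derive_geometry(sites: pd.DataFrame, cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Fill ``geometry_derived`` and ``area_derived_km2``.

    Point sites become a disc of radius ``cfg.point_buffer_m`` built in the
    point's local metric frame; polygon sites keep their reported geometry.
    Areas are recomputed on the (authalic-sphere) ellipsoid model.
    """
    cfg = cfg or PipelineConfig()
    derived, areas = [], []
    for g in sites["geometry_reported"]:
        if g.geom_type == "Point":
            validate_lonlat(g.x, g.y)
            d = buffer_metric(g, cfg.point_buffer_m)
        else:
            d = g
        derived.append(d)
        areas.append(geodesic_area_km2(d))
    out = sites.copy()
    out["geometry_derived"] = derived
    out["area_derived_km2"] = areas
    return out


# -- writing ------------------------------------------------------------------

def write_sites(sites: pd.DataFrame, path, format: str | None = None) -> None:
    """Write a site table as GeoJSON, CSV (WKT geometries) or GeoParquet."""
    path = Path(path)
    fmt = _detect_format(path, format)
    geom_cols = [c for c in ("geometry_reported", "geometry_derived") if c in sites.columns]
    if fmt == "geojson":
        features = []
        for _, row in sites.iterrows():
            props = {}
            for col, val in row.items():
                if col in geom_cols:
                    continue
                if isinstance(val, pd.Timestamp):
                    val = val.isoformat()
                elif isinstance(val, (np.floating, np.integer)):
                    val = val.item()
                elif val is pd.NaT or (isinstance(val, float) and np.isnan(val)):
                    val = None
                props[col] = val
            for c in geom_cols:
                if c != "geometry_reported" and row[c] is not None:
                    props[c] = shapely.to_wkt(row[c], rounding_precision=-1)
            features.append({
                "type": "Feature",
                "geometry": _mapping(row["geometry_reported"]),
                "properties": props,
            })
        path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    elif fmt == "csv":
        df = sites.copy()
        for c in geom_cols:
            df[c] = [shapely.to_wkt(g, rounding_precision=-1) if g is not None else ""
                     for g in df[c]]
        df.to_csv(path, index=False)
    elif fmt == "parquet":
        import pyarrow as pa
        import pyarrow.parquet as pq

        df = sites.copy()
        for c in geom_cols:
            df[c] = [shapely.to_wkb(g) if g is not None else None for g in df[c]]
        table = pa.Table.from_pandas(df, preserve_index=False)
        geo_meta = {
            "version": "1.0.0",
            "primary_column": "geometry_reported",
            "columns": {c: {"encoding": "WKB", "geometry_types": []} for c in geom_cols},
        }
        table = table.replace_schema_metadata(
            {**(table.schema.metadata or {}), b"geo": json.dumps(geo_meta).encode()}
        )
        pq.write_table(table, path)
    else:
        raise ValueError(f"unsupported output format: {fmt!r}")


__all__ = [
    "SITE_COLUMNS", "PLANTING_DATE_TYPES", "read_sites", "harmonize_sites",
    "explode_multipolygons", "derive_geometry", "write_sites",
    "parse_area_km2", "parse_planting_date",
]
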