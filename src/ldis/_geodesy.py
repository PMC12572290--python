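"""Lightweight geodesy for WGS84 lon/lat geometries.

Two primitives cover everything the pipeline needs:

* equal-area polygon area via the authalic sphere (the ellipsoid is mapped
  area-preservingly onto a sphere of radius ``R_AUTHALIC`` by replacing
  geodetic with authalic latitudes), and
* a per-feature local metric frame — spherical azimuthal-equidistant
  projection centred on the feature — for buffering, perimeters, lengths and
  any operation that needs honest metres.

Both treat polygon edges as straight in the projected coordinates, which for
planting-site- and district-scale features is far below the tolerances used
anywhere in the package.
"""

from __future__ import annotations

import math

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform as _shapely_transform

WGS84_A = 6_378_137.0
WGS84_F = 1.0 / 298.257223563
_E2 = WGS84_F * (2.0 - WGS84_F)
_E = math.sqrt(_E2)


def _q(sinphi: np.ndarray) -> np.ndarray:
    # Snyder (1987) eq. 3-12
    return (1.0 - _E2) * (
        sinphi / (1.0 - _E2 * sinphi**2)
        - (1.0 / (2.0 * _E)) * np.log((1.0 - _E * sinphi) / (1.0 + _E * sinphi))
    )


_QP = float(_q(np.array(1.0)))
R_AUTHALIC = WGS84_A * math.sqrt(_QP / 2.0)  # ~6371007.18 m


def authalic_sin_lat(lat_deg: np.ndarray) -> np.ndarray:
    """sin of the authalic latitude for geodetic latitude in degrees."""
    sinphi = np.sin(np.radians(np.asarray(lat_deg, dtype=float)))
    return np.clip(_q(sinphi) / _QP, -1.0, 1.0)


def ring_area_m2(lon_deg: np.ndarray, lat_deg: np.ndarray) -> float:
    """Signed area (m^2) of one closed lon/lat ring, positive counter-clockwise."""
    lam = np.radians(np.asarray(lon_deg, dtype=float))
    sin_xi = authalic_sin_lat(lat_deg)
    if lam[0] != lam[-1] or sin_xi[0] != sin_xi[-1]:
        lam = np.append(lam, lam[0])
        sin_xi = np.append(sin_xi, sin_xi[0])
    dlam = np.diff(lam)
    # wrap antimeridian-crossing edges the short way
    dlam = (dlam + math.pi) % (2.0 * math.pi) - math.pi
    return 0.5 * R_AUTHALIC**2 * float(np.sum(dlam * (sin_xi[:-1] + sin_xi[1:])))


def geodesic_area_km2(geom: BaseGeometry) -> float:
    """Unsigned area in km^2 of a (multi)polygon in WGS84 lon/lat."""
    if geom.is_empty:
        return 0.0
    total = 0.0
    polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
    for poly in polys:
        if poly.geom_type != "Polygon":
            continue
        x, y = poly.exterior.coords.xy
        total += abs(ring_area_m2(np.asarray(x), np.asarray(y)))
        for interior in poly.interiors:
            x, y = interior.coords.xy
            total -= abs(ring_area_m2(np.asarray(x), np.asarray(y)))
    return total / 1e6


class LocalMetricFrame:
    """Azimuthal-equidistant frame (metres) centred at (lon0, lat0).

    Distances from the centre are exact on the sphere; distortion over the
    few-kilometre extents handled here is negligible.
    """

    def __init__(self, lon0: float, lat0: float, radius: float | None = None):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        if radius is None:
            # Gaussian mean radius sqrt(M*N) at the centre: directional scale
            # errors of the sphere model cancel to first order in areas
            s2 = math.sin(math.radians(lat0)) ** 2
            n = WGS84_A / math.sqrt(1.0 - _E2 * s2)
            m = WGS84_A * (1.0 - _E2) / (1.0 - _E2 * s2) ** 1.5
            radius = math.sqrt(m * n)
        self.radius = radius
        self._lam0 = math.radians(lon0)
        self._phi0 = math.radians(lat0)
        self._sin0 = math.sin(self._phi0)
        self._cos0 = math.cos(self._phi0)

    @classmethod
    def around(cls, geom: BaseGeometry) -> "LocalMetricFrame":
        c = geom.centroid
        return cls(c.x, c.y)

    def forward_xy(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        sinp, cosp = np.sin(phi), np.cos(phi)
        dlam = lam - self._lam0
        cos_c = np.clip(self._sin0 * sinp + self._cos0 * cosp * np.cos(dlam), -1.0, 1.0)
        c = np.arccos(cos_c)
        sin_c = np.sin(c)
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(sin_c > 1e-12, c / np.where(sin_c == 0, 1.0, sin_c), 1.0)
        x = self.radius * k * cosp * np.sin(dlam)
        y = self.radius * k * (self._cos0 * sinp - self._sin0 * cosp * np.cos(dlam))
        return x, y

    def inverse_lonlat(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        rho = np.hypot(x, y)
        c = rho / self.radius
        sin_c, cos_c = np.sin(c), np.cos(c)
        with np.errstate(invalid="ignore", divide="ignore"):
            safe_rho = np.where(rho == 0, 1.0, rho)
            phi = np.arcsin(
                np.clip(cos_c * self._sin0 + y * sin_c * self._cos0 / safe_rho, -1.0, 1.0)
            )
            lam = self._lam0 + np.arctan2(
                x * sin_c, safe_rho * self._cos0 * cos_c - y * self._sin0 * sin_c
            )
        phi = np.where(rho == 0, self._phi0, phi)
        lam = np.where(rho == 0, self._lam0, lam)
        return np.degrees(lam), np.degrees(phi)

    def to_metric(self, geom: BaseGeometry) -> BaseGeometry:
        return _shapely_transform(self.forward_xy, geom)

    def to_wgs84(self, geom: BaseGeometry) -> BaseGeometry:
        return _shapely_transform(self.inverse_lonlat, geom)


def buffer_metric(geom: BaseGeometry, distance_m: float, quad_segs: int = 32) -> BaseGeometry:
    """Buffer a WGS84 geometry by a metric distance, in its local frame."""
    frame = LocalMetricFrame.around(geom)
    return frame.to_wgs84(frame.to_metric(geom).buffer(distance_m, quad_segs=quad_segs))


def geodesic_length_km(geom: BaseGeometry) -> float:
    """Length in km of a WGS84 line geometry."""
    if geom.is_empty:
        return 0.0
    frame = LocalMetricFrame.around(geom)
    return frame.to_metric(geom).length / 1e3


def metric_perimeter_and_area(geom: BaseGeometry) -> tuple[float, float]:
    """(perimeter m, area m^2) of a polygon in its local metric frame."""
    frame = LocalMetricFrame.around(geom)
    g = frame.to_metric(geom)
    return g.length, g.area


def validate_lonlat(lon: float, lat: float) -> None:
    if not (-180.0 <= lon <= 180.0) or not (-90.0 <= lat <= 90.0):
        raise ValueError(f"coordinates out of WGS84 range: lon={lon}, lat={lat}")


__all__ = [
    "R_AUTHALIC",
    "LocalMetricFrame",
    "authalic_sin_lat",
    "buffer_metric",
    "geodesic_area_km2",
    "geodesic_length_km",
    "metric_perimeter_and_area",
    "ring_area_m2",
    "validate_lonlat",
]
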