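"""Minimal geo-raster container and zonal statistics.

A :class:`Raster` is a numpy array on a north-up regular lon/lat grid with a
top-left anchor and cell size in degrees.  IO covers GeoTIFF (via tifffile,
writing the standard georeferencing tags) and the plain-text ESRI ASCII grid.

Zonal extraction uses exact cell/polygon intersection areas (every cell
contributes its overlap area, weighted by cos(latitude) so weights are
proportional to true ground area) rather than cell-centre membership — small
sites would otherwise suffer quantisation artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

_TAG_PIXELSCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
# GTModelType=geographic, GTRasterType=PixelIsArea, GeographicType=WGS84
_GEOKEYS_WGS84 = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


@dataclass
class Raster:
    """North-up lon/lat grid. data is (rows, cols) or (bands, rows, cols)."""

    data: np.ndarray
    x0: float  # west edge (lon)
    y0: float  # north edge (lat)
    dx: float  # cell width, degrees (> 0)
    dy: float  # cell height, degrees (> 0)
    nodata: float | None = None
    band_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError("raster data must be 2-D or (bands, rows, cols)")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes must be positive")

    # -- geometry of the grid -------------------------------------------------
    @property
    def n_bands(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[-2:]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        rows, cols = self.shape
        return (self.x0, self.y0 - rows * self.dy, self.x0 + cols * self.dx, self.y0)

    def band(self, key: int | str) -> np.ndarray:
        if isinstance(key, str):
            key = self.band_names.index(key)
        return self.data if self.data.ndim == 2 else self.data[key]

    def window(self, geom: BaseGeometry) -> tuple[slice, slice]:
        """Row/col slices covering the geometry's bounding box."""
        minx, miny, maxx, maxy = geom.bounds
        rows, cols = self.shape
        c0 = max(0, int(math.floor((minx - self.x0) / self.dx)))
        c1 = min(cols, int(math.ceil((maxx - self.x0) / self.dx)))
        r0 = max(0, int(math.floor((self.y0 - maxy) / self.dy)))
        r1 = min(rows, int(math.ceil((self.y0 - miny) / self.dy)))
        return slice(r0, max(r0, r1)), slice(c0, max(c0, c1))

    # -- IO -------------------------------------------------------------------
    def to_geotiff(self, path) -> None:
        import tifffile

        arr = self.data if self.data.ndim == 2 else np.moveaxis(self.data, 0, -1)
        extratags = [
            (_TAG_PIXELSCALE, "d", 3, (self.dx, self.dy, 0.0)),
            (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, self.x0, self.y0, 0.0)),
            (_TAG_GEOKEYS, "H", len(_GEOKEYS_WGS84), _GEOKEYS_WGS84),
        ]
        meta = {"band_names": self.band_names, "nodata": self.nodata}
        tifffile.imwrite(
            path, arr, photometric="minisblack", extratags=extratags,
            metadata=meta, planarconfig="contig" if arr.ndim == 3 else None,
        )

    @classmethod
    def from_geotiff(cls, path) -> "Raster":
        import json

        import tifffile

        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            arr = tif.asarray()
            scale = page.tags[_TAG_PIXELSCALE].value
            tie = page.tags[_TAG_TIEPOINT].value
            meta = {}
            desc = page.tags.get("ImageDescription")
            if desc is not None:
                try:
                    meta = json.loads(desc.value)
                except (ValueError, TypeError):
                    meta = {}
        if arr.ndim == 3:  # (rows, cols, bands) -> (bands, rows, cols)
            arr = np.moveaxis(arr, -1, 0)
        return cls(
            arr, x0=tie[3], y0=tie[4], dx=scale[0], dy=scale[1],
            nodata=meta.get("nodata"), band_names=list(meta.get("band_names") or []),
        )

    def to_ascii(self, path) -> None:
        if self.data.ndim != 2:
            raise ValueError("ASCII grid supports a single band only")
        if not math.isclose(self.dx, self.dy, rel_tol=1e-9):
            raise ValueError("ASCII grid requires square cells")
        rows, cols = self.shape
        nodata = self.nodata if self.nodata is not None else -9999
        header = (
            f"ncols {cols}\nnrows {rows}\nxllcorner {self.x0!r}\n"
            f"yllcorner {self.y0 - rows * self.dy!r}\ncellsize {self.dx!r}\n"
            f"NODATA_value {nodata}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.data, fmt="%.10g")

    @classmethod
    def from_ascii(cls, path) -> "Raster":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            data = np.loadtxt(fh)
        rows = int(header["nrows"])
        cell = header["cellsize"]
        return cls(
            data.reshape(rows, int(header["ncols"])),
            x0=header["xllcorner"], y0=header["yllcorner"] + rows * cell,
            dx=cell, dy=cell, nodata=header.get("nodata_value"),
        )


@dataclass
class ZonalCells:
    """Cells of one raster intersecting one polygon.

    rows/cols index into the full raster; weights are proportional to the
    true ground area of each cell/polygon intersection and sum to the covered
    site area (in cos-weighted square degrees).  ``coverage`` is the covered
    share of the polygon, ~1 when the site lies inside the raster extent.
    """

    rows: np.ndarray
    cols: np.ndarray
    weights: np.ndarray
    coverage: float

    def __len__(self) -> int:
        return len(self.rows)

    def values(self, band: np.ndarray) -> np.ndarray:
        return band[self.rows, self.cols]


def zonal_cells(raster: Raster, geom: BaseGeometry) -> ZonalCells:
    """Exact area-weighted cell membership of ``geom`` in ``raster``."""
    rs, cs = raster.window(geom)
    n_r, n_c = rs.stop - rs.start, cs.stop - cs.start
    geom_area = shapely.area(geom) * math.cos(math.radians(geom.centroid.y))
    if n_r == 0 or n_c == 0:
        e = np.empty(0, dtype=int)
        return ZonalCells(e, e, np.empty(0), 0.0)
    cols = np.arange(cs.start, cs.stop)
    rows = np.arange(rs.start, rs.stop)
    west = raster.x0 + cols * raster.dx
    north = raster.y0 - rows * raster.dy
    ww, nn = np.meshgrid(west, north)
    boxes = shapely.box(
        ww.ravel(), (nn - raster.dy).ravel(), (ww + raster.dx).ravel(), nn.ravel()
    )
    inter = shapely.area(shapely.intersection(boxes, geom)).reshape(n_r, n_c)
    lat_centres = north - raster.dy / 2.0
    weights = inter * np.cos(np.radians(lat_centres))[:, None]
    rr, cc = np.nonzero(inter > 0)
    w = weights[rr, cc]
    covered = float(w.sum())
    coverage = covered / geom_area if geom_area > 0 else 0.0
    return ZonalCells(rr + rs.start, cc + cs.start, w, min(coverage, 1.0))


def zonal_mean(raster: Raster, geom: BaseGeometry, band: int | str = 0,
               valid: np.ndarray | None = None) -> tuple[float, int]:
    """Area-weighted mean of a band over a polygon.

    ``valid`` is an optional boolean mask on the full grid; cells where it is
    False (or where the band is NaN/nodata) are dropped.  Returns
    (mean, n contributing cells); mean is NaN when nothing contributes.
    """
    cells = zonal_cells(raster, geom)
    if len(cells) == 0:
        return float("nan"), 0
    vals = cells.values(np.asarray(raster.band(band), dtype=float))
    keep = np.isfinite(vals)
    if raster.nodata is not None:
        keep &= vals != raster.nodata
    if valid is not None:
        keep &= cells.values(valid)
    if not keep.any():
        return float("nan"), 0
    w = cells.weights[keep]
    return float(np.average(vals[keep], weights=w)), int(keep.sum())


__all__ = ["Raster", "ZonalCells", "zonal_cells", "zonal_mean"]
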