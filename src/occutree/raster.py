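"""Multiband rasters: tiling, point sampling, clipping, aggregation, DEM products.

A :class:`RasterGrid` is a stack of equally shaped 2-D arrays with a simple
north-up affine transform (origin at the top-left corner, square pixels in
degrees) and a nodata sentinel.  Monthly climate layers are the motivating
case for multiband stacks (12 bands, one per month).

Terrain products (slope, aspect, hillshade) use Horn's 3x3 finite
differences, with the x pixel size scaled by cos(latitude) per row to
convert degrees to metres.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry
from shapely.prepared import prep

from .errors import EmptyClipError, ParameterError
from .projection import AUTHALIC_RADIUS_M

#: metres per degree of arc on the authalic sphere
METRES_PER_DEGREE = AUTHALIC_RADIUS_M * math.pi / 180.0

DEFAULT_NODATA = -9999.0


@dataclass
class RasterGrid:
    """Gridded coverage: bands (band, row, col), north-up georeferencing."""

    bands: np.ndarray            # float array, shape (nbands, nrows, ncols)
    west: float                  # longitude of the left edge
    north: float                 # latitude of the top edge
    resolution: float            # pixel size, degrees (square pixels)
    nodata: float = DEFAULT_NODATA
    band_names: tuple[str, ...] = ()
    name: str = "raster"
    units: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.bands, dtype=float)
        if arr.ndim == 2:
            arr = arr[None, :, :]
        if arr.ndim != 3:
            raise ParameterError("bands must be a 2-D or 3-D array")
        self.bands = arr
        if not self.band_names:
            self.band_names = tuple(f"band_{i + 1}" for i in range(arr.shape[0]))
        if len(self.band_names) != arr.shape[0]:
            raise ParameterError("band_names length must match band count")

    # -- geometry -------------------------------------------------------------

    @property
    def nbands(self) -> int:
        return self.bands.shape[0]

    @property
    def nrows(self) -> int:
        return self.bands.shape[1]

    @property
    def ncols(self) -> int:
        return self.bands.shape[2]

    @property
    def south(self) -> float:
        return self.north - self.nrows * self.resolution

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.resolution

    def pixel_for(self, lon: float, lat: float) -> tuple[int, int] | None:
        """(row, col) of the pixel containing the point; None outside."""
        if not (self.west <= lon <= self.east and self.south <= lat <= self.north):
            return None
        col = min(int((lon - self.west) / self.resolution), self.ncols - 1)
        row = min(int((self.north - lat) / self.resolution), self.nrows - 1)
        return row, col

    def pixel_centre(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.west + (col + 0.5) * self.resolution,
            self.north - (row + 0.5) * self.resolution,
        )

    def mask(self) -> np.ndarray:
        """Boolean (band, row, col) array, True where data is valid."""
        return self.bands != self.nodata


# -- tiling -----------------------------------------------------------------

@dataclass
class TileSet:
    """Regular tiling of a raster; reassembles bit-exactly."""

    tiles: list[tuple[tuple[int, int], RasterGrid]]
    source_shape: tuple[int, int, int]
    block_size: int
    west: float
    north: float
    resolution: float
    nodata: float
    band_names: tuple[str, ...] = ()


def tile(raster: RasterGrid, block_size: int) -> TileSet:
    """Partition into ``block_size`` x ``block_size`` tiles (edge tiles smaller)."""
    if block_size < 1:
        raise ParameterError("block_size must be >= 1")
    tiles = []
    for ti, r0 in enumerate(range(0, raster.nrows, block_size)):
        for tj, c0 in enumerate(range(0, raster.ncols, block_size)):
            block = raster.bands[:, r0:r0 + block_size, c0:c0 + block_size].copy()
            tiles.append((
                (ti, tj),
                RasterGrid(
                    block,
                    west=raster.west + c0 * raster.resolution,
                    north=raster.north - r0 * raster.resolution,
                    resolution=raster.resolution,
                    nodata=raster.nodata,
                    band_names=raster.band_names,
                ),
            ))
    return TileSet(tiles, raster.bands.shape, block_size,
                   raster.west, raster.north, raster.resolution,
                   raster.nodata, raster.band_names)


def untile(tileset: TileSet) -> RasterGrid:
    """Reassemble the source raster (bit-exact round-trip with :func:`tile`)."""
    out = np.empty(tileset.source_shape, dtype=float)
    bs = tileset.block_size
    for (ti, tj), block in tileset.tiles:
        r0, c0 = ti * bs, tj * bs
        out[:, r0:r0 + block.nrows, c0:c0 + block.ncols] = block.bands
    return RasterGrid(out, tileset.west, tileset.north, tileset.resolution,
                      tileset.nodata, tileset.band_names)


# -- sampling and aggregation -------------------------------------------------

def sample_at_points(
    raster: RasterGrid, points: Sequence[tuple[float, float]]
) -> pd.DataFrame:
    """Containing-pixel lookup: one row per point, one column per band.

    Out-of-extent points and nodata pixels yield NaN.
    """
    rows = []
    for lon, lat in points:
        pix = raster.pixel_for(lon, lat)
        if pix is None:
            rows.append([np.nan] * raster.nbands)
        else:
            vals = raster.bands[:, pix[0], pix[1]]
            rows.append([np.nan if v == raster.nodata else float(v) for v in vals])
    return pd.DataFrame(rows, columns=list(raster.band_names))


def clip_to_polygon(raster: RasterGrid, polygon: BaseGeometry) -> RasterGrid:
    """Minimal window around ``polygon``; outside-centre pixels set to nodata."""
    minx, miny, maxx, maxy = polygon.bounds
    c0 = max(0, int(math.floor((minx - raster.west) / raster.resolution)))
    c1 = min(raster.ncols, int(math.ceil((maxx - raster.west) / raster.resolution)))
    r0 = max(0, int(math.floor((raster.north - maxy) / raster.resolution)))
    r1 = min(raster.nrows, int(math.ceil((raster.north - miny) / raster.resolution)))
    if c0 >= c1 or r0 >= r1:
        raise EmptyClipError("polygon does not intersect the raster extent")
    window = raster.bands[:, r0:r1, c0:c1].copy()
    prepared = prep(polygon)
    keep = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    for i in range(r1 - r0):
        for j in range(c1 - c0):
            lon, lat = raster.pixel_centre(r0 + i, c0 + j)
            keep[i, j] = prepared.intersects(Point(lon, lat))
    if not keep.any():
        raise EmptyClipError("no pixel centre falls inside the polygon")
    window[:, ~keep] = raster.nodata
    return RasterGrid(
        window,
        west=raster.west + c0 * raster.resolution,
        north=raster.north - r0 * raster.resolution,
        resolution=raster.resolution,
        nodata=raster.nodata,
        band_names=raster.band_names,
        name=raster.name,
        units=raster.units,
    )


_AGG = {
    "mean": np.nanmean,
    "min": np.nanmin,
    "max": np.nanmax,
    "sum": np.nansum,
}


def band_aggregate(raster: RasterGrid, stat: str = "mean") -> RasterGrid:
    """Per-pixel statistic across bands, ignoring nodata.

    A pixel is nodata in the result only when it is nodata in every band
    (e.g., mean-annual from 12 monthly bands).
    """
    if stat not in _AGG:
        raise ParameterError(f"stat must be one of {sorted(_AGG)}, got {stat!r}")
    data = np.where(raster.mask(), raster.bands, np.nan)
    all_nan = ~raster.mask().any(axis=0)
    with warnings.catch_warnings():
        # all-nodata pixels are filled with the sentinel below
        warnings.simplefilter("ignore", category=RuntimeWarning)
        out = _AGG[stat](data, axis=0)
    out = np.where(all_nan, raster.nodata, out)
    return RasterGrid(out[None], raster.west, raster.north, raster.resolution,
                      raster.nodata, (stat,), f"{raster.name}_{stat}", raster.units)


# -- DEM derivatives ----------------------------------------------------------

def dem_derivatives(
    elevation: RasterGrid,
    sun_azimuth: float = 315.0,
    sun_altitude: float = 45.0,
) -> dict[str, RasterGrid]:
    """Slope, aspect, hillshade from a single-band elevation raster.

    Horn's 3x3 method; slope in degrees, aspect in degrees clockwise from
    north (flat pixels get aspect nodata), hillshade scaled 0-255.  Border
    pixels are nodata.  Pixel size converts to metres with a per-row
    cos(latitude) scaling of the x resolution.
    """
    if elevation.nbands != 1:
        raise ParameterError("dem_derivatives expects a single-band raster")
    z = elevation.bands[0]
    nr, nc = z.shape
    nd = elevation.nodata
    dy = elevation.resolution * METRES_PER_DEGREE

    slope = np.full((nr, nc), nd)
    aspect = np.full((nr, nc), nd)
    shade = np.full((nr, nc), nd)
    zen = math.radians(90.0 - sun_altitude)
    az = math.radians(sun_azimuth)

    for i in range(1, nr - 1):
        _, lat = elevation.pixel_centre(i, 0)
        dx = elevation.resolution * METRES_PER_DEGREE * math.cos(math.radians(lat))
        w = z[i - 1:i + 2, :]
        if (w == nd).any():
            valid_rows = ~np.isclose(w, nd).any(axis=0)
        else:
            valid_rows = np.ones(nc, dtype=bool)
        for j in range(1, nc - 1):
            if not (valid_rows[j - 1] and valid_rows[j] and valid_rows[j + 1]):
                continue
            a, b, c = z[i - 1, j - 1], z[i - 1, j], z[i - 1, j + 1]
            d, f = z[i, j - 1], z[i, j + 1]
            g, h, k = z[i + 1, j - 1], z[i + 1, j], z[i + 1, j + 1]
            dzdx = ((c + 2 * f + k) - (a + 2 * d + g)) / (8.0 * dx)
            dzdy = ((g + 2 * h + k) - (a + 2 * b + c)) / (8.0 * dy)  # southward +
            rise = math.hypot(dzdx, dzdy)
            slope_rad = math.atan(rise)
            slope[i, j] = math.degrees(slope_rad)
            if rise > 0:
                # downslope direction, clockwise from north
                asp = math.degrees(math.atan2(-dzdx, dzdy))
                aspect[i, j] = asp % 360.0
                asp_rad = math.radians(aspect[i, j])
            else:
                asp_rad = 0.0
            lum = (math.cos(zen) * math.cos(slope_rad)
                   + math.sin(zen) * math.sin(slope_rad) * math.cos(az - asp_rad))
            shade[i, j] = max(0.0, 255.0 * lum)
    common = dict(west=elevation.west, north=elevation.north,
                  resolution=elevation.resolution, nodata=nd)
    return {
        "slope": RasterGrid(slope, name="slope", units="degrees", **common),
        "aspect": RasterGrid(aspect, name="aspect", units="degrees", **common),
        "hillshade": RasterGrid(shade, name="hillshade", units="", **common),
    }


# -- tree-linked extraction ----------------------------------------------------

def tree_raster_table(tree, rasters: dict[str, RasterGrid]) -> pd.DataFrame:
    """Point-based extraction over a tree's occurrences.

    One row per occurrence (indexed by id), one column per (raster, band):
    ``<raster>_<band>`` for multiband inputs, the raster name alone for
    single-band ones.
    """
    occurrences = tree.occurrences
    points = [(o.longitude, o.latitude) for o in occurrences]
    frames = []
    for name, raster in rasters.items():
        table = sample_at_points(raster, points)
        if raster.nbands == 1:
            table.columns = [name]
        else:
            table.columns = [f"{name}_{b}" for b in raster.band_names]
        frames.append(table)
    out = pd.concat(frames, axis=1) if frames else pd.DataFrame(index=range(len(points)))
    out.index = pd.Index([o.id for o in occurrences], name="occurrence_id")
    return out


def tree_raster_area(tree, raster: RasterGrid, grid) -> RasterGrid:
    """Area-based extraction: clip ``raster`` to the union of the tree's cells."""
    if tree.is_empty:
        raise EmptyClipError("tree has no occurrences")
    return clip_to_polygon(raster, tree.geometry(grid))


# -- I/O -----------------------------------------------------------------------

def write_ascii_grid(raster: RasterGrid, path, band: int = 0) -> None:
    """Write one band as an ESRI ASCII grid (plain-text, exact for integers)."""
    data = raster.bands[band]
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.west!r}\n")
        fh.write(f"yllcorner {raster.south!r}\n")
        fh.write(f"cellsize {raster.resolution!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        for row in data:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path, name: str = "raster") -> RasterGrid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    data = np.array(rows, dtype=float)
    res = header["cellsize"]
    return RasterGrid(
        data,
        west=header["xllcorner"],
        north=header["yllcorner"] + header["nrows"] * res,
        resolution=res,
        nodata=header.get("nodata_value", DEFAULT_NODATA),
        name=name,
    )


def write_png(raster: RasterGrid, path, band: int = 0) -> None:
    """Quick-look PNG of one band (grayscale, nodata transparent)."""
    from PIL import Image

    data = raster.bands[band].astype(float)
    valid = data != raster.nodata
    lo = data[valid].min() if valid.any() else 0.0
    hi = data[valid].max() if valid.any() else 1.0
    scale = (hi - lo) or 1.0
    grey = np.zeros_like(data, dtype=np.uint8)
    grey[valid] = np.round(255 * (data[valid] - lo) / scale).astype(np.uint8)
    alpha = np.where(valid, 255, 0).astype(np.uint8)
    Image.fromarray(np.dstack([grey, grey, grey, alpha]), "RGBA").save(path)
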