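"""Geographic grid rasters on a regular lon/lat lattice.

A :class:`GridRaster` is the common currency of the diversity-mapping,
suitability-modelling and prioritization stages: a rectangular grid of
cells in geographic (longitude/latitude) coordinates, indexed row-major
from the north-west corner, with cell values addressed at cell centers.
Missing cells are encoded as NaN in memory and as an explicit nodata
sentinel on disk (ESRI ASCII grid, a plain-text interchange format).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridRaster",
    "standardize_raster",
    "merge_rasters_max",
    "read_ascii_grid",
    "write_ascii_grid",
]

#: nodata sentinel used in ESRI ASCII output
NODATA = -9999.0


@dataclass
class GridRaster:
    """A rectangular lon/lat grid holding one value per cell.

    Parameters
    ----------
    extent : tuple of float
        ``(lon_min, lon_max, lat_min, lat_max)`` in decimal degrees.
    resolution_arcmin : float
        Cell edge length in arc-minutes; must divide both extent spans.
    values : ndarray of shape (nrows, ncols)
        Cell values; NaN marks nodata. Row 0 is the northernmost row.
    """

    extent: tuple[float, float, float, float]
    resolution_arcmin: float
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lon_min, lon_max, lat_min, lat_max = self.extent
        if lon_max <= lon_min or lat_max <= lat_min:
            raise ValueError("degenerate extent: zero or negative area")
        if self.resolution_arcmin <= 0:
            raise ValueError("resolution must be positive")
        res = self.resolution_arcmin / 60.0
        ncols = (lon_max - lon_min) / res
        nrows = (lat_max - lat_min) / res
        if abs(ncols - round(ncols)) > 1e-8 or abs(nrows - round(nrows)) > 1e-8:
            raise ValueError(
                f"resolution {self.resolution_arcmin}' does not divide extent {self.extent}"
            )
        self._ncols = int(round(ncols))
        self._nrows = int(round(nrows))
        if self.values is None:
            self.values = np.full((self._nrows, self._ncols), np.nan)
        else:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.shape != (self._nrows, self._ncols):
                raise ValueError(
                    f"values shape {self.values.shape} != grid shape "
                    f"{(self._nrows, self._ncols)}"
                )

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self._nrows, self._ncols

    @property
    def resolution_deg(self) -> float:
        return self.resolution_arcmin / 60.0

    def same_geometry(self, other: "GridRaster") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.extent, other.extent)
            and np.isclose(self.resolution_arcmin, other.resolution_arcmin)
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (lon, lat) center coordinates as 2-D arrays of grid shape."""
        lon_min, _, _, lat_max = self.extent
        res = self.resolution_deg
        lons = lon_min + (np.arange(self._ncols) + 0.5) * res
        lats = lat_max - (np.arange(self._nrows) + 0.5) * res
        return np.meshgrid(lons, lats)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing a point (half-open cells, NW origin)."""
        lon_min, lon_max, lat_min, lat_max = self.extent
        if not (lon_min <= lon <= lon_max and lat_min <= lat <= lat_max):
            raise ValueError(f"point ({lon}, {lat}) outside extent {self.extent}")
        res = self.resolution_deg
        col = min(int((lon - lon_min) / res), self._ncols - 1)
        row = min(int((lat_max - lat) / res), self._nrows - 1)
        return row, col

    def contains(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        lon_min, lon_max, lat_min, lat_max = self.extent
        return (
            (np.asarray(lon) >= lon_min)
            & (np.asarray(lon) <= lon_max)
            & (np.asarray(lat) >= lat_min)
            & (np.asarray(lat) <= lat_max)
        )

    # -- values -------------------------------------------------------------

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def like(self, values: np.ndarray | None = None) -> "GridRaster":
        """A new raster with this geometry and the given (or all-nodata) values."""
        v = None if values is None else np.array(values, dtype=float)
        return GridRaster(self.extent, self.resolution_arcmin, v)

    def sample(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Values at the cells containing the given points (NaN outside extent)."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        out = np.full(lon.shape, np.nan)
        inside = self.contains(lon, lat)
        lon_min, lon_max, lat_min, lat_max = self.extent
        res = self.resolution_deg
        col = np.clip(((lon - lon_min) / res).astype(int), 0, self._ncols - 1)
        row = np.clip(((lat_max - lat) / res).astype(int), 0, self._nrows - 1)
        out[inside] = self.values[row[inside], col[inside]]
        return out


def standardize_raster(r: GridRaster) -> GridRaster:
    """Rescale valid cell values linearly to [0, 1].

    A constant raster maps to all zeros so that a layer with no spatial
    contrast cannot dominate a subsequent max-merge.
    """
    vals = r.valid_values
    if vals.size == 0:
        raise ValueError("raster has no valid cells")
    lo, hi = float(vals.min()), float(vals.max())
    out = np.full(r.shape, np.nan)
    if hi == lo:
        out[r.valid_mask] = 0.0
    else:
        out[r.valid_mask] = (r.values[r.valid_mask] - lo) / (hi - lo)
    return r.like(out)


def merge_rasters_max(a: GridRaster, b: GridRaster) -> GridRaster:
    """Cell-wise maximum of two rasters, keeping a value where either has one."""
    if not a.same_geometry(b):
        raise ValueError("raster geometries do not match")
    out = np.fmax(a.values, b.values)  # fmax ignores NaN where one side is valid
    return a.like(out)


# -- ESRI ASCII grid I/O ----------------------------------------------------


def write_ascii_grid(r: GridRaster, path) -> None:
    """Write a raster as an ESRI ASCII grid (text, xllcorner convention)."""
    lon_min, _, lat_min, _ = r.extent
    nrows, ncols = r.shape
    vals = np.where(r.valid_mask, r.values, NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {lon_min!r}\n")
        fh.write(f"yllcorner {lat_min!r}\n")
        fh.write(f"cellsize {r.resolution_deg!r}\n")
        fh.write(f"NODATA_value {NODATA!r}\n")
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path) -> GridRaster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        body = fh.read()
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    res_deg = header["cellsize"]
    lon_min = header["xllcorner"]
    lat_min = header["yllcorner"]
    nodata = header["nodata_value"]
    vals = np.loadtxt(io.StringIO(body)).reshape(nrows, ncols)
    vals = np.where(vals == nodata, np.nan, vals)
    extent = (lon_min, lon_min + ncols * res_deg, lat_min, lat_min + nrows * res_deg)
    return GridRaster(extent, res_deg * 60.0, vals)
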