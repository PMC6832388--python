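"""Gridded-raster containers and geometry utilities.

All layers in the pipeline — nighttime-light brightness, NDVI, surface
fluxes, species counts — live on regular geographic (lat/lon) grids.  The
:class:`GridRaster` container stores one 2-D layer together with its cell
edges; :class:`TimeRaster` stacks one layer per year on a shared grid.

Conventions
-----------
* Cell values are cell means registered at cell centers; interpolation is
  always center-to-center.
* Grids are stored south-to-north (ascending ``lat_edges``) regardless of
  file row order.
* Pixel areas are spherical-quadrilateral areas on a sphere of radius
  6371.0 km.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import numpy.ma as ma

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "GridRaster",
    "TimeRaster",
    "read_raster",
    "write_raster",
    "read_time_raster",
    "write_time_raster",
    "resample_bilinear",
    "pixel_area_km2",
    "EARTH_RADIUS_KM",
]


@dataclasses.dataclass
class GridRaster:
    """One 2-D geographic layer with explicit cell geometry.

    Parameters
    ----------
    values : ndarray or MaskedArray, shape (nlat, nlon)
        Layer values; row 0 is the southernmost row.
    lat_edges : ndarray, shape (nlat + 1,)
        Strictly increasing cell edges in degrees, within [-90, 90].
    lon_edges : ndarray, shape (nlon + 1,)
        Strictly increasing cell edges in degrees, spanning at most 360.
    nodata : scalar, optional
        Sentinel used on disk; in memory nodata cells are masked.
    name : str
        Layer label (e.g. ``"ndvi"``, ``"lights"``).
    """

    values: np.ndarray
    lat_edges: np.ndarray
    lon_edges: np.ndarray
    nodata: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.lat_edges = np.asarray(self.lat_edges, dtype=float)
        self.lon_edges = np.asarray(self.lon_edges, dtype=float)
        if not isinstance(self.values, ma.MaskedArray):
            self.values = np.asarray(self.values)
            if self.nodata is not None:
                self.values = ma.masked_equal(self.values, self.nodata)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        nlat, nlon = self.values.shape
        if self.lat_edges.shape != (nlat + 1,) or self.lon_edges.shape != (nlon + 1,):
            raise ValueError(
                f"edge arrays ({self.lat_edges.size}, {self.lon_edges.size}) do not "
                f"match value shape {self.values.shape}"
            )
        if np.any(np.diff(self.lat_edges) <= 0) or np.any(np.diff(self.lon_edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if self.lat_edges[0] < -90 - 1e-9 or self.lat_edges[-1] > 90 + 1e-9:
            raise ValueError("lat edges must lie within [-90, 90]")
        if self.lon_edges[-1] - self.lon_edges[0] > 360 + 1e-9:
            raise ValueError("lon span exceeds 360 degrees")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    def same_grid(self, other: "GridRaster", atol: float = 1e-9) -> bool:
        return (
            self.lat_edges.shape == other.lat_edges.shape
            and self.lon_edges.shape == other.lon_edges.shape
            and np.allclose(self.lat_edges, other.lat_edges, atol=atol)
            and np.allclose(self.lon_edges, other.lon_edges, atol=atol)
        )

    def filled_values(self, fill=np.nan) -> np.ndarray:
        """Values as a plain float array with masked cells set to *fill*."""
        return ma.filled(ma.masked_invalid(self.values).astype(float), fill)

    def valid_mask(self) -> np.ndarray:
        v = ma.masked_invalid(self.values)
        return ~ma.getmaskarray(v)

    def with_values(self, values, name: str | None = None) -> "GridRaster":
        return GridRaster(values, self.lat_edges, self.lon_edges,
                          nodata=self.nodata, name=self.name if name is None else name)


@dataclasses.dataclass
class TimeRaster:
    """Annual stack of :class:`GridRaster` layers on a shared grid."""

    years: np.ndarray
    layers: list[GridRaster]

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        if len(self.layers) != self.years.size:
            raise ValueError("one layer per year required")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        first = self.layers[0]
        for layer in self.layers[1:]:
            if not layer.same_grid(first):
                raise ValueError("all layers must share identical cell geometry")

    @property
    def grid(self) -> GridRaster:
        return self.layers[0]

    def stack(self) -> ma.MaskedArray:
        """(nyears, nlat, nlon) masked stack."""
        return ma.stack([ma.masked_invalid(l.values).astype(float) for l in self.layers])


# ---------------------------------------------------------------------------
# GeoTIFF I/O (single band; geotags written and read directly)
# ---------------------------------------------------------------------------

_TAG_PIXEL_SCALE = 33550   # ModelPixelScaleTag
_TAG_TIEPOINT = 33922      # ModelTiepointTag
_TAG_GDAL_NODATA = 42113


def write_raster(raster: GridRaster, path: str | Path) -> None:
    """Write a GridRaster to a single-band GeoTIFF (rows north-to-south)."""
    import tifffile

    path = Path(path)
    dlat = np.diff(raster.lat_edges)
    dlon = np.diff(raster.lon_edges)
    if not (np.allclose(dlat, dlat[0]) and np.allclose(dlon, dlon[0])):
        raise ValueError("GeoTIFF export requires a uniform grid")
    data = np.asarray(ma.getdata(raster.values))
    mask = ma.getmaskarray(ma.masked_invalid(raster.values))
    nodata = raster.nodata
    if mask.any():
        if nodata is None:
            nodata = -9999.0 if np.issubdtype(data.dtype, np.floating) else -9999
        data = data.copy()
        data[mask] = nodata
    # top row is northernmost in the file
    data = data[::-1]
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (float(dlon[0]), float(dlat[0]), 0.0)),
        # tie raster origin (0,0) to the NW corner
        (_TAG_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, float(raster.lon_edges[0]), float(raster.lat_edges[-1]), 0.0)),
    ]
    if nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(nodata)))
    tifffile.imwrite(path, data, extratags=extratags,
                     metadata=None, description=raster.name or None)


def read_raster(path: str | Path, layer_name: str = "") -> GridRaster:
    """Read one gridded layer from GeoTIFF or NetCDF.

    Dispatches on extension: ``.nc`` → NetCDF, otherwise GeoTIFF.  Nodata
    cells come back masked; geometry is reconstructed from file metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".nc", ".cdf", ".netcdf"}:
        return _read_raster_netcdf(path, layer_name)
    return _read_raster_tiff(path, layer_name)


def _read_raster_tiff(path: Path, layer_name: str) -> GridRaster:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = page.asarray()
            tags = {t.code: t.value for t in page.tags.values()}
            description = page.description or ""
    except Exception as exc:  # noqa: BLE001 - normalize to format error
        raise ValueError(f"unreadable GeoTIFF: {path}") from exc
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise ValueError(f"missing georeferencing metadata in {path}")
    sx, sy, _ = tags[_TAG_PIXEL_SCALE]
    tie = tags[_TAG_TIEPOINT]
    lon0, lat_top = tie[3], tie[4]
    nlat, nlon = data.shape
    lon_edges = lon0 + sx * np.arange(nlon + 1)
    lat_edges = (lat_top - sy * nlat) + sy * np.arange(nlat + 1)
    data = data[::-1]  # back to south-to-north
    nodata = None
    if _TAG_GDAL_NODATA in tags:
        text = tags[_TAG_GDAL_NODATA]
        nodata = float(text) if np.issubdtype(data.dtype, np.floating) else int(float(text))
    return GridRaster(data, lat_edges, lon_edges, nodata=nodata,
                      name=layer_name or description)


# ---------------------------------------------------------------------------
# NetCDF3 I/O (CF-style lat/lon[/time]) via scipy
# ---------------------------------------------------------------------------

def write_time_raster(series: TimeRaster, path: str | Path, var_name: str = "ndvi") -> None:
    """Write an annual stack to a CF-style NetCDF3 file (time, lat, lon)."""
    from scipy.io import netcdf_file

    grid = series.grid
    fill = -9999.0
    with netcdf_file(str(path), "w") as nc:
        nc.createDimension("time", series.years.size)
        nc.createDimension("lat", grid.shape[0])
        nc.createDimension("lon", grid.shape[1])
        vt = nc.createVariable("time", "i", ("time",))
        vt[:] = series.years
        vt.units = b"year"
        vlat = nc.createVariable("lat", "d", ("lat",))
        vlat[:] = grid.lat_centers
        vlat.units = b"degrees_north"
        vlon = nc.createVariable("lon", "d", ("lon",))
        vlon[:] = grid.lon_centers
        vlon.units = b"degrees_east"
        var = nc.createVariable(var_name, "d", ("time", "lat", "lon"))
        var._FillValue = fill
        var[:] = ma.filled(series.stack(), fill)
        # cell edges stored explicitly so the geometry round-trips exactly
        nc.createDimension("lat_edge", grid.shape[0] + 1)
        nc.createDimension("lon_edge", grid.shape[1] + 1)
        nc.createVariable("lat_edges", "d", ("lat_edge",))[:] = grid.lat_edges
        nc.createVariable("lon_edges", "d", ("lon_edge",))[:] = grid.lon_edges


def write_raster_netcdf(raster: GridRaster, path: str | Path, var_name: str = "layer") -> None:
    """Write a single layer as a (lat, lon) NetCDF3 file."""
    series = TimeRaster(np.array([0]), [raster])
    write_time_raster(series, path, var_name=var_name)


def _nc_edges(nc, centers: np.ndarray, edge_key: str) -> np.ndarray:
    if edge_key in nc.variables:
        return nc.variables[edge_key][:].copy()
    # reconstruct edges from uniform centers
    step = centers[1] - centers[0] if centers.size > 1 else 1.0
    return np.concatenate([[centers[0] - step / 2], centers + step / 2])


def read_time_raster(path: str | Path, var_name: str = "ndvi") -> TimeRaster:
    from scipy.io import netcdf_file

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with netcdf_file(str(path), "r", mmap=False) as nc:
        if var_name not in nc.variables:
            raise ValueError(f"variable {var_name!r} not in {path}")
        if "lat" not in nc.variables or "lon" not in nc.variables:
            raise ValueError(f"missing lat/lon coordinates in {path}")
        lat = nc.variables["lat"][:].copy()
        lon = nc.variables["lon"][:].copy()
        lat_edges = _nc_edges(nc, lat, "lat_edges")
        lon_edges = _nc_edges(nc, lon, "lon_edges")
        var = nc.variables[var_name]
        data = var[:].copy().astype(float)
        fill = getattr(var, "_FillValue", None)
        years = nc.variables["time"][:].copy() if "time" in nc.variables else np.array([0])
    if data.ndim == 2:
        data = data[None]
    flip = lat_edges[0] > lat_edges[-1]
    if flip:
        lat_edges = lat_edges[::-1].copy()
        data = data[:, ::-1]
    layers = []
    for k in range(data.shape[0]):
        vals = ma.masked_invalid(data[k])
        if fill is not None:
            vals = ma.masked_values(vals, float(fill))
        layers.append(GridRaster(vals, lat_edges, lon_edges, name=var_name))
    return TimeRaster(np.asarray(years, dtype=int), layers)


def _read_raster_netcdf(path: Path, layer_name: str) -> GridRaster:
    series = read_time_raster(path, var_name=layer_name or "layer")
    raster = series.layers[0]
    raster.name = layer_name
    return raster


# ---------------------------------------------------------------------------
# Resampling and areas
# ---------------------------------------------------------------------------

def _axis_weights(src_centers: np.ndarray, targets: np.ndarray):
    """Lower neighbor index and fractional position for 1-D linear interp.

    Targets outside the outermost centers clamp to the nearest center
    (constant extrapolation), matching cell-mean registration.
    """
    idx = np.searchsorted(src_centers, targets) - 1
    idx = np.clip(idx, 0, max(src_centers.size - 2, 0))
    if src_centers.size == 1:
        return idx, np.zeros_like(targets, dtype=float)
    span = src_centers[idx + 1] - src_centers[idx]
    frac = (targets - src_centers[idx]) / span
    return idx, np.clip(frac, 0.0, 1.0)


def resample_bilinear(
    src: GridRaster,
    target_lat_edges: Sequence[float],
    target_lon_edges: Sequence[float],
    nodata_policy: str = "renormalize",
) -> GridRaster:
    """Bilinear center-to-center resampling onto a target grid.

    Nodata handling follows *nodata_policy*:

    - ``"renormalize"`` (default): weights are renormalized over the valid
      members of the 4-neighbor stencil; a cell is masked only when all
      four contributors are invalid.  This avoids eroding coastlines when
      coarsening to 0.75 degrees.
    - ``"mask"``: any invalid contributor masks the target cell.
    """
    if nodata_policy not in {"renormalize", "mask"}:
        raise ValueError(f"unknown nodata policy {nodata_policy!r}")
    target_lat_edges = np.asarray(target_lat_edges, dtype=float)
    target_lon_edges = np.asarray(target_lon_edges, dtype=float)
    if (target_lat_edges[-1] <= src.lat_edges[0] or target_lat_edges[0] >= src.lat_edges[-1]
            or target_lon_edges[-1] <= src.lon_edges[0] or target_lon_edges[0] >= src.lon_edges[-1]):
        raise ValueError("target grid does not overlap source grid")

    tlat = 0.5 * (target_lat_edges[:-1] + target_lat_edges[1:])
    tlon = 0.5 * (target_lon_edges[:-1] + target_lon_edges[1:])
    iy, fy = _axis_weights(src.lat_centers, tlat)
    ix, fx = _axis_weights(src.lon_centers, tlon)

    vals = src.filled_values(np.nan)
    valid = np.isfinite(vals).astype(float)
    vals0 = np.where(np.isfinite(vals), vals, 0.0)

    iy0 = iy[:, None]
    iy1 = np.minimum(iy + 1, vals.shape[0] - 1)[:, None]
    ix0 = ix[None, :]
    ix1 = np.minimum(ix + 1, vals.shape[1] - 1)[None, :]
    fy_ = fy[:, None]
    fx_ = fx[None, :]

    w = (
        ((1 - fy_) * (1 - fx_), iy0, ix0),
        ((1 - fy_) * fx_, iy0, ix1),
        (fy_ * (1 - fx_), iy1, ix0),
        (fy_ * fx_, iy1, ix1),
    )
    num = np.zeros((tlat.size, tlon.size))
    den = np.zeros_like(num)
    wmax = np.zeros_like(num)  # total weight, to detect any-invalid for "mask"
    for weight, r, c in w:
        v = vals0[r, c]
        ok = valid[r, c]
        num += weight * ok * v
        den += weight * ok
        wmax += weight
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    if nodata_policy == "mask":
        bad = den < wmax - 1e-12
    else:
        bad = den <= 0
    out = ma.masked_array(out, mask=bad | ~np.isfinite(out))
    return GridRaster(out, target_lat_edges, target_lon_edges, name=src.name)


def pixel_area_km2(raster: GridRaster) -> GridRaster:
    """Per-cell spherical-quadrilateral area in km^2.

    area = R^2 * dlambda * (sin(phi_2) - sin(phi_1)) with R = 6371 km; sums
    to the sphere surface (~5.1007e8 km^2) over a full-globe grid.
    """
    lat = np.deg2rad(raster.lat_edges)
    lon = np.deg2rad(raster.lon_edges)
    band = EARTH_RADIUS_KM**2 * (np.sin(lat[1:]) - np.sin(lat[:-1]))
    area = band[:, None] * np.diff(lon)[None, :]
    return GridRaster(area, raster.lat_edges, raster.lon_edges, name="pixel_area_km2")
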