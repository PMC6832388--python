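"""City delineation from nighttime-light rasters.

Cities are spatially contiguous lighted pixels whose digital number (DN,
0-63) meets a brightness threshold (default DN >= 12).  Each connected
component is one city; its size is the sum of member pixel areas.  City
counts are summarized in a Zipf-style spectrum over exponentially widening
size bins (base 2 km^2).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import numpy.ma as ma
import pandas as pd
from scipy import ndimage

from .grid import GridRaster

__all__ = [
    "CityTable",
    "CitySizeSpectrum",
    "extract_cities",
    "city_size",
    "size_spectrum",
    "city_mask",
    "fit_spectrum_slope",
]


@dataclasses.dataclass
class CityTable:
    """Labeled city components plus a per-city record table.

    ``labels`` is a 2-D integer raster (0 = background, j >= 1 the city
    label); ``table`` has one row per city with columns ``label``,
    ``pixel_count`` and, after :func:`city_size`, ``size_km2``.
    """

    labels: np.ndarray
    table: pd.DataFrame
    lat_edges: np.ndarray
    lon_edges: np.ndarray

    @property
    def n_cities(self) -> int:
        return len(self.table)

    def member_indices(self, label: int) -> np.ndarray:
        """(n, 2) row/col indices of the pixels belonging to one city."""
        return np.argwhere(self.labels == label)


@dataclasses.dataclass
class CitySizeSpectrum:
    """City counts in exponentially widening size bins.

    Bin 0 covers (0, base); bin k >= 1 covers [base*2^(k-1), base*2^k) km^2.
    """

    edges_km2: np.ndarray
    counts: np.ndarray
    base_km2: float
    stats: pd.DataFrame | None = None

    @property
    def n_bins(self) -> int:
        return self.counts.size


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError("connectivity must be 4 or 8")


def extract_cities(
    light: GridRaster,
    dn_threshold: int = 12,
    connectivity: int = 8,
    wrap_lon: bool = False,
) -> CityTable:
    """Label contiguous lighted components with DN >= *dn_threshold*.

    Parameters
    ----------
    light : GridRaster
        Integer DN raster with values in [0, 63]; masked cells are treated
        as unlit.
    dn_threshold : int
        Inclusive brightness threshold defining city membership.
    connectivity : {4, 8}
        Pixel adjacency; 8 (default) joins diagonal neighbors.
    wrap_lon : bool
        Join components across the +/-180 degree seam when the grid spans
        the full longitude circle.
    """
    if not (0 <= dn_threshold <= 63):
        raise ValueError(f"dn_threshold must be in [0, 63], got {dn_threshold}")
    vals = ma.filled(ma.masked_invalid(light.values), -1)
    if np.any((vals > 63) | (vals < -1)):
        raise ValueError("light DN values must lie in [0, 63]")
    lit = vals >= dn_threshold
    labels, n = ndimage.label(lit, structure=_structure(connectivity))
    if wrap_lon and labels.shape[1] > 1:
        labels = _merge_across_seam(labels, connectivity)
    labs, counts = np.unique(labels[labels > 0], return_counts=True)
    table = pd.DataFrame({
        "label": labs.astype(int),
        "pixel_count": counts.astype(int),
        "size_km2": np.full(labs.size, np.nan),
    })
    return CityTable(labels, table, light.lat_edges.copy(), light.lon_edges.copy())


def _merge_across_seam(labels: np.ndarray, connectivity: int) -> np.ndarray:
    """Union labels touching opposite longitude edges of a wrapped grid."""
    left, right = labels[:, 0], labels[:, -1]
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    nrow = labels.shape[0]
    offsets = (0,) if connectivity == 4 else (-1, 0, 1)
    for r in range(nrow):
        if right[r] == 0:
            continue
        for dr in offsets:
            rr = r + dr
            if 0 <= rr < nrow and left[rr] > 0:
                union(right[r], left[rr])
    if not parent:
        return labels
    out = labels.copy()
    roots = {lab: find(lab) for lab in np.unique(labels[labels > 0])}
    # compress to consecutive labels
    uniq = sorted(set(roots.values()))
    remap = {root: k + 1 for k, root in enumerate(uniq)}
    lut = np.zeros(labels.max() + 1, dtype=labels.dtype)
    for lab, root in roots.items():
        lut[lab] = remap[root]
    out = lut[labels]
    return out


def city_size(table: CityTable, areas: GridRaster) -> CityTable:
    """Fill ``size_km2`` as the sum of member pixel areas per city."""
    if (areas.lat_edges.shape != table.lat_edges.shape
            or not np.allclose(areas.lat_edges, table.lat_edges)
            or not np.allclose(areas.lon_edges, table.lon_edges)):
        raise ValueError("area raster is not on the city grid")
    labs = table.table["label"].to_numpy()
    sizes = ndimage.sum_labels(np.asarray(ma.getdata(areas.values), dtype=float),
                               table.labels, index=labs)
    new = table.table.copy()
    new["size_km2"] = sizes
    return CityTable(table.labels, new, table.lat_edges, table.lon_edges)


def size_spectrum(table: CityTable, base_km2: float = 2.0) -> CitySizeSpectrum:
    """Bin city sizes into the exponential spectrum.

    Bin k covers [base*2^(k-1), base*2^k) with bin 0 = (0, base); counts
    over all bins sum to the number of cities.
    """
    if base_km2 <= 0:
        raise ValueError("base_km2 must be positive")
    if table.n_cities == 0:
        raise ValueError("empty CityTable")
    sizes = table.table["size_km2"].to_numpy(dtype=float)
    if np.any(~np.isfinite(sizes)):
        raise ValueError("city sizes not computed; run city_size first")
    kmax = int(np.ceil(np.log2(max(sizes.max() / base_km2, 1.0)))) + 1
    edges = np.concatenate([[0.0], base_km2 * 2.0 ** np.arange(kmax + 1)])
    counts, _ = np.histogram(sizes, bins=edges)
    return CitySizeSpectrum(edges, counts, base_km2)


def fit_spectrum_slope(spectrum: CitySizeSpectrum, min_count: int = 5) -> float:
    """Least-squares slope of log2(count) versus bin index.

    For city sizes drawn from a discrete power law with exponent s the
    expected slope is (1 - s): counts in bins doubling in width fall off by
    a factor 2^(1-s) per bin.  Only bins with at least *min_count* cities
    enter the fit.
    """
    k = np.arange(spectrum.n_bins)
    good = spectrum.counts >= min_count
    if good.sum() < 2:
        raise ValueError("too few populated bins to fit a slope")
    return float(np.polyfit(k[good], np.log2(spectrum.counts[good]), 1)[0])


def city_mask(
    table: CityTable,
    target_lat_edges: np.ndarray,
    target_lon_edges: np.ndarray,
    areas: GridRaster | None = None,
) -> GridRaster:
    """Fractional city cover of each target cell.

    The fraction is the lighted (city) area among the fine-resolution
    pixels whose centers fall inside the coarse cell, area-weighted when
    *areas* is given and pixel-counted otherwise.  Cells receiving no fine
    pixels are masked.
    """
    target_lat_edges = np.asarray(target_lat_edges, dtype=float)
    target_lon_edges = np.asarray(target_lon_edges, dtype=float)
    lat_c = 0.5 * (table.lat_edges[:-1] + table.lat_edges[1:])
    lon_c = 0.5 * (table.lon_edges[:-1] + table.lon_edges[1:])
    iy = np.searchsorted(target_lat_edges, lat_c, side="right") - 1
    ix = np.searchsorted(target_lon_edges, lon_c, side="right") - 1
    ny, nx = target_lat_edges.size - 1, target_lon_edges.size - 1
    ok_y = (iy >= 0) & (iy < ny)
    ok_x = (ix >= 0) & (ix < nx)
    w = (np.asarray(ma.getdata(areas.values), dtype=float)
         if areas is not None else np.ones(table.labels.shape))
    inside = ok_y[:, None] & ok_x[None, :]
    flat = (np.clip(iy, 0, ny - 1)[:, None] * nx + np.clip(ix, 0, nx - 1)[None, :])
    city = (table.labels > 0).astype(float)
    total = np.zeros(ny * nx)
    lit = np.zeros(ny * nx)
    np.add.at(total, flat[inside], w[inside])
    np.add.at(lit, flat[inside], (w * city)[inside])
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = lit / total
    frac = ma.masked_array(frac.reshape(ny, nx), mask=(total.reshape(ny, nx) == 0))
    return GridRaster(frac, target_lat_edges, target_lon_edges, name="city_cover")
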