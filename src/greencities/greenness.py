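"""NDVI-conditioned statistics of species, threat and greenness variability.

Everything here stratifies co-registered rasters by climatological NDVI in
half-open bins [T, T + width) with width 0.1 by default, for three strata:
cities, non-cities, and land = city + non-city.  The central quantity is
the threatened species indicator — threatened species count divided by
species abundance — aggregated as a ratio of sums within each bin so that
area and population effects cancel.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import numpy.ma as ma
import pandas as pd
from scipy import ndimage

from .cities import CitySizeSpectrum, CityTable
from .grid import GridRaster, TimeRaster

__all__ = [
    "StratumMask",
    "threatened_indicator",
    "coefficient_of_variability",
    "bin_stats",
    "ndvi_percentage",
    "city_percentage",
    "table1_summary",
    "size_conditioned_stats",
    "GLOBAL_VERTEBRATE_TABLE",
]

#: Global per-taxon vertebrate abundance and threatened counts for the
#: representative year 2010 (units: gridded species-richness counts).
GLOBAL_VERTEBRATE_TABLE = pd.DataFrame(
    {
        "abundance": [283_256, 4_376_655, 1_270_883],
        "threatened": [2_892, 92_513, 49_782],
    },
    index=pd.Index(["amphibian", "birds", "mammal"], name="taxon"),
)


@dataclasses.dataclass
class StratumMask:
    """Boolean city / non-city partition of the land mask.

    Invariant: city | non_city == land and city & non_city is empty, so
    any statistic over land equals the city and non-city contributions
    combined.
    """

    city: np.ndarray
    land: np.ndarray

    def __post_init__(self) -> None:
        self.city = np.asarray(self.city, dtype=bool)
        self.land = np.asarray(self.land, dtype=bool)
        if self.city.shape != self.land.shape:
            raise ValueError("city and land masks must share a shape")
        if np.any(self.city & ~self.land):
            raise ValueError("city mask must be a subset of the land mask")

    @property
    def non_city(self) -> np.ndarray:
        return self.land & ~self.city

    def stratum(self, name: str) -> np.ndarray:
        try:
            return {"city": self.city, "non_city": self.non_city,
                    "land": self.land}[name]
        except KeyError:
            raise ValueError(f"unknown stratum {name!r}") from None


def threatened_indicator(threatened, abundance):
    """Threatened species count over species abundance.

    Masked (never silently divided) where abundance is zero.  Works on
    scalars or arrays; arrays come back masked.
    """
    t = np.asarray(threatened, dtype=float)
    a = np.asarray(abundance, dtype=float)
    if np.any(t < 0) or np.any(a < 0):
        raise ValueError("counts must be non-negative")
    zero = a == 0
    if np.ndim(a) == 0:
        if zero:
            warnings.warn("abundance is zero; indicator undefined", stacklevel=2)
            return np.nan
        return float(t / a)
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cells with zero abundance masked",
                      stacklevel=2)
    return ma.masked_array(np.divide(t, a, out=np.zeros_like(t), where=~zero),
                           mask=zero)


def coefficient_of_variability(series: TimeRaster, ddof: int = 0,
                               min_years: int = 3) -> GridRaster:
    """Per-pixel ratio of annual-NDVI standard deviation to its mean.

    The standard deviation uses population normalization (ddof=0) by
    default.  Pixels with fewer than *min_years* valid years or with a
    non-positive mean are masked.
    """
    stack = series.stack()
    n_valid = (~ma.getmaskarray(stack)).sum(axis=0)
    mu = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=ddof)
    bad = (n_valid < min_years) | ma.getmaskarray(mu) | (ma.filled(mu, 0.0) <= 0)
    if np.any(n_valid < min_years):
        warnings.warn("pixels with fewer than "
                      f"{min_years} valid years masked", stacklevel=2)
    cv = ma.masked_array(ma.filled(sd / ma.masked_array(mu, mask=bad), np.nan),
                         mask=bad)
    return series.grid.with_values(cv, name="ndvi_cv")


def _ndvi_bin_edges(bin_width: float) -> np.ndarray:
    n = int(round(1.0 / bin_width))
    # rounding keeps thresholds like 0.3 exactly representable in tables
    return np.round(np.linspace(0.0, n * bin_width, n + 1), 10)


def _bin_index(ndvi: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open [T, T+w) bin index; NDVI exactly 1 joins the last bin."""
    idx = np.searchsorted(edges, ndvi, side="right") - 1
    idx[np.isclose(ndvi, edges[-1])] = edges.size - 2
    return idx


def bin_stats(
    ndvi_clim: GridRaster,
    abundance: GridRaster,
    threatened: GridRaster,
    mask: np.ndarray,
    areas: GridRaster | None = None,
    cv: GridRaster | None = None,
    bin_width: float = 0.1,
    stratum: str = "land",
) -> pd.DataFrame:
    """Per-NDVI-bin species statistics over one stratum.

    Within each half-open bin [T, T + width) the abundance and threatened
    counts are summed, the indicator is the ratio of those sums (not the
    mean of per-pixel ratios), and the variability coefficient is the
    area-weighted mean over bin pixels.  Negative NDVI is excluded as
    non-vegetated.  Empty bins are retained with NaN statistics.
    """
    edges = _ndvi_bin_edges(bin_width)
    ndvi = ndvi_clim.filled_values(np.nan)
    ab = abundance.filled_values(np.nan)
    th = threatened.filled_values(np.nan)
    w = (np.asarray(ma.getdata(areas.values), dtype=float)
         if areas is not None else np.ones_like(ndvi))
    cvv = cv.filled_values(np.nan) if cv is not None else None

    sel = (np.asarray(mask, bool) & np.isfinite(ndvi) & (ndvi >= 0)
           & (ndvi <= edges[-1]) & np.isfinite(ab) & np.isfinite(th))
    idx = _bin_index(ndvi[sel], edges)
    nb = edges.size - 1
    ab_sum = np.bincount(idx, weights=ab[sel], minlength=nb)
    th_sum = np.bincount(idx, weights=th[sel], minlength=nb)
    area = np.bincount(idx, weights=w[sel], minlength=nb)
    npix = np.bincount(idx, minlength=nb)
    if cvv is not None:
        ok = sel & np.isfinite(cvv)
        i2 = _bin_index(ndvi[ok], edges)
        cw = np.bincount(i2, weights=(w * np.nan_to_num(cvv))[ok], minlength=nb)
        ca = np.bincount(i2, weights=w[ok], minlength=nb)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv_mean = np.where(ca > 0, cw / ca, np.nan)
    else:
        cv_mean = np.full(nb, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        indicator = np.where(ab_sum > 0, th_sum / ab_sum, np.nan)
        area_frac = area / area.sum() if area.sum() > 0 else np.full(nb, np.nan)
    out = pd.DataFrame({
        "ndvi_lo": edges[:-1],
        "ndvi_hi": edges[1:],
        "n_pixels": npix,
        "abundance": ab_sum,
        "threatened": th_sum,
        "indicator": indicator,
        "cv_mean": cv_mean,
        "area_km2": area,
        "area_fraction": area_frac,
    })
    out["stratum"] = stratum
    return out


def ndvi_percentage(
    ndvi_clim: GridRaster,
    region_mask: np.ndarray,
    areas: GridRaster | None = None,
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Fraction of region area per NDVI bin (plus out-of-range remainder).

    Fractions over the bins and the ``out_of_range`` row (NDVI < 0 or
    masked NDVI) sum to one exactly.
    """
    region_mask = np.asarray(region_mask, bool)
    if not region_mask.any():
        raise ValueError("empty region mask")
    edges = _ndvi_bin_edges(bin_width)
    ndvi = ndvi_clim.filled_values(np.nan)
    w = (np.asarray(ma.getdata(areas.values), dtype=float)
         if areas is not None else np.ones_like(ndvi))
    total = w[region_mask].sum()
    if total <= 0:
        raise ValueError("region has zero area")
    in_range = region_mask & np.isfinite(ndvi) & (ndvi >= 0) & (ndvi <= edges[-1])
    idx = _bin_index(ndvi[in_range], edges)
    area = np.bincount(idx, weights=w[in_range], minlength=edges.size - 1)
    frac = area / total
    rows = pd.DataFrame({
        "ndvi_lo": edges[:-1], "ndvi_hi": edges[1:], "fraction": frac,
    })
    rows.attrs["out_of_range"] = float(1.0 - frac.sum())
    return rows


def city_percentage(
    ndvi_clim: GridRaster,
    city_mask: np.ndarray,
    areas: GridRaster | None = None,
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Fraction of total city area falling in each NDVI bin."""
    city_mask = np.asarray(city_mask, bool)
    if not city_mask.any():
        raise ValueError("city mask is empty")
    return ndvi_percentage(ndvi_clim, city_mask, areas=areas, bin_width=bin_width)


def table1_summary(
    regions: dict[str, np.ndarray],
    taxa: dict[str, tuple[GridRaster, GridRaster]],
    strata: StratumMask,
    areas: GridRaster,
) -> pd.DataFrame:
    """Regional urbanization/vertebrate summary in the style of a country
    comparison table.

    For each region: land-area percentage of the global land, per-taxon
    abundance and threatened percentages of the global totals, city and
    non-city area percentages of the regional land, and per-taxon
    threatened counts inside/outside cities as percentages of the regional
    taxon total (in + out = 100 by construction).
    """
    w = np.asarray(ma.getdata(areas.values), dtype=float)
    glob_land = strata.land
    glob_area = w[glob_land].sum()
    glob_ab = {}
    glob_th = {}
    for taxon, (ab, th) in taxa.items():
        a = np.nan_to_num(ab.filled_values(np.nan))
        t = np.nan_to_num(th.filled_values(np.nan))
        glob_ab[taxon] = a[glob_land].sum()
        glob_th[taxon] = t[glob_land].sum()
    rows = []
    for name, rmask in regions.items():
        rmask = np.asarray(rmask, bool) & glob_land
        row: dict[str, float | str] = {"region": name}
        rarea = w[rmask].sum()
        row["land_area_pct_of_global"] = 100 * rarea / glob_area
        ab_tot = th_tot = 0.0
        for taxon, (ab, th) in taxa.items():
            a = np.nan_to_num(ab.filled_values(np.nan))
            t = np.nan_to_num(th.filled_values(np.nan))
            ab_r, th_r = a[rmask].sum(), t[rmask].sum()
            ab_tot += ab_r
            th_tot += th_r
            row[f"abundance_pct_{taxon}"] = (
                100 * ab_r / glob_ab[taxon] if glob_ab[taxon] else np.nan)
            row[f"threatened_pct_{taxon}"] = (
                100 * th_r / glob_th[taxon] if glob_th[taxon] else np.nan)
            in_city = t[rmask & strata.city].sum()
            row[f"threatened_in_city_pct_{taxon}"] = (
                100 * in_city / th_r if th_r else np.nan)
            row[f"threatened_out_city_pct_{taxon}"] = (
                100 * (th_r - in_city) / th_r if th_r else np.nan)
        row["abundance_pct_all"] = 100 * ab_tot / sum(glob_ab.values())
        row["threatened_pct_all"] = 100 * th_tot / sum(glob_th.values())
        city_area = w[rmask & strata.city].sum()
        row["city_pct"] = 100 * city_area / rarea if rarea else np.nan
        row["non_city_pct"] = 100 * (rarea - city_area) / rarea if rarea else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")


def size_conditioned_stats(
    cities: CityTable,
    spectrum: CitySizeSpectrum,
    ndvi_clim: GridRaster,
    abundance: GridRaster,
    threatened: GridRaster,
    areas: GridRaster | None = None,
) -> pd.DataFrame:
    """Per-size-bin distribution of per-city greenness and threat.

    For each city: the area-weighted mean NDVI over its footprint and its
    threatened indicator (threatened sum / abundance sum over the
    footprint).  Cities are then grouped by the exponential size bins and
    mean/median/quartiles reported per bin; empty bins stay with NaN.
    """
    if cities.n_cities == 0:
        raise ValueError("empty CityTable")
    labs = cities.table["label"].to_numpy()
    w = (np.asarray(ma.getdata(areas.values), dtype=float)
         if areas is not None else np.ones(cities.labels.shape))
    ndvi = np.nan_to_num(ndvi_clim.filled_values(np.nan))
    ab = np.nan_to_num(abundance.filled_values(np.nan))
    th = np.nan_to_num(threatened.filled_values(np.nan))
    wsum = ndimage.sum_labels(w, cities.labels, index=labs)
    ndvi_mean = ndimage.sum_labels(w * ndvi, cities.labels, index=labs) / wsum
    ab_sum = ndimage.sum_labels(ab, cities.labels, index=labs)
    th_sum = ndimage.sum_labels(th, cities.labels, index=labs)
    with np.errstate(invalid="ignore", divide="ignore"):
        indicator = np.where(ab_sum > 0, th_sum / ab_sum, np.nan)
    sizes = cities.table["size_km2"].to_numpy(dtype=float)
    bin_idx = np.clip(np.searchsorted(spectrum.edges_km2, sizes, side="right") - 1,
                      0, spectrum.n_bins - 1)
    rows = []
    for k in range(spectrum.n_bins):
        inb = bin_idx == k
        row = {
            "size_lo_km2": spectrum.edges_km2[k],
            "size_hi_km2": spectrum.edges_km2[k + 1],
            "n_cities": int(inb.sum()),
        }
        for label, vals in (("ndvi", ndvi_mean[inb]), ("indicator", indicator[inb])):
            vals = vals[np.isfinite(vals)]
            if vals.size:
                row[f"{label}_mean"] = float(vals.mean())
                row[f"{label}_median"] = float(np.median(vals))
                row[f"{label}_q25"] = float(np.percentile(vals, 25))
                row[f"{label}_q75"] = float(np.percentile(vals, 75))
            else:
                for stat in ("mean", "median", "q25", "q75"):
                    row[f"{label}_{stat}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
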