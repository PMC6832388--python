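"""City-versus-land NDVI trend comparison and green/brown classification.

Annual-mean NDVI series are formed per stratum over pixels whose
climatological NDVI lies in a fixed interval, fit by ordinary least
squares against year, and compared through the slope ratio
slope_city / slope_land.  A city markedly out-greening its land average
(ratio at least ``green_ratio_min`` with a positive city slope) is a
*green* city effect; land-like trends (ratio within ``brown_band`` of 1)
or a non-increasing city slope mark a *brown* effect; anything else is
indeterminate.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import numpy.ma as ma
import pandas as pd
from scipy import stats

from .grid import GridRaster, TimeRaster

__all__ = ["TrendComparison", "annual_stratum_mean", "linear_trend", "compare_trends"]

#: land slopes smaller than this (NDVI/yr) make the ratio undefined
SLOPE_EPS = 1e-6


@dataclasses.dataclass
class TrendComparison:
    """Paired city/land regression summary over one NDVI interval."""

    interval: tuple[float, float]
    years: np.ndarray
    city_mean: np.ndarray
    land_mean: np.ndarray
    slope_city: float
    slope_land: float
    intercept_city: float
    intercept_land: float
    resid_sd_city: float
    resid_sd_land: float
    ratio: float                  # NaN when slope_land ~ 0
    effect: str                   # green | brown | indeterminate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "interval_lo": self.interval[0],
            "interval_hi": self.interval[1],
            "slope_city": self.slope_city,
            "slope_land": self.slope_land,
            "ratio": self.ratio,
            "effect": self.effect,
        }])


def annual_stratum_mean(
    series: TimeRaster,
    stratum_mask: np.ndarray,
    interval: tuple[float, float],
    ndvi_clim: GridRaster,
    areas: GridRaster | None = None,
) -> pd.Series:
    """Area-weighted mean NDVI per year over one stratum and NDVI interval.

    The selection is fixed over time: pixels belong when the mask is set
    and the *climatological* NDVI lies in [lo, hi).
    """
    lo, hi = interval
    clim = ndvi_clim.filled_values(np.nan)
    sel = (np.asarray(stratum_mask, bool) & np.isfinite(clim)
           & (clim >= lo) & (clim < hi))
    if not sel.any():
        raise ValueError(f"no pixels in stratum for NDVI interval [{lo}, {hi})")
    w = (np.asarray(ma.getdata(areas.values), dtype=float)
         if areas is not None else np.ones_like(clim))
    means = []
    for layer in series.layers:
        vals = ma.masked_invalid(layer.values)
        wv = np.where(sel & ~ma.getmaskarray(vals), w, 0.0)
        tot = wv.sum()
        means.append(float((ma.filled(vals, 0.0) * wv).sum() / tot) if tot > 0
                     else np.nan)
    return pd.Series(means, index=pd.Index(series.years, name="year"), name="ndvi")


def linear_trend(table: pd.Series) -> tuple[float, float, float]:
    """OLS fit of annual means against year.

    Returns (slope in NDVI/yr, intercept at year 0, residual SD).
    Requires at least 3 years.
    """
    years = np.asarray(table.index, dtype=float)
    vals = np.asarray(table.to_numpy(), dtype=float)
    ok = np.isfinite(vals)
    if ok.sum() < 3:
        raise ValueError("need at least 3 years for a trend")
    res = stats.linregress(years[ok], vals[ok])
    resid = vals[ok] - (res.intercept + res.slope * years[ok])
    return float(res.slope), float(res.intercept), float(resid.std(ddof=0))


def compare_trends(
    series: TimeRaster,
    city_mask: np.ndarray,
    land_mask: np.ndarray,
    interval: tuple[float, float],
    ndvi_clim: GridRaster,
    areas: GridRaster | None = None,
    green_ratio_min: float = 2.0,
    brown_band: float = 0.25,
) -> TrendComparison:
    """Fit city and land trends over one NDVI interval and classify.

    effect = green when ratio >= green_ratio_min and slope_city > 0;
    brown when |ratio - 1| <= brown_band or slope_city <= 0; otherwise
    indeterminate.  When |slope_land| < 1e-6 NDVI/yr the ratio is left
    undefined and the decision falls back on the signs of the slopes.
    """
    cm = annual_stratum_mean(series, city_mask, interval, ndvi_clim, areas)
    lm = annual_stratum_mean(series, land_mask, interval, ndvi_clim, areas)
    sc, ic, rc = linear_trend(cm)
    sl, il, rl = linear_trend(lm)
    if abs(sl) < SLOPE_EPS:
        ratio = np.nan
        effect = "green" if sc > 0 else "brown"
    else:
        ratio = sc / sl
        if ratio >= green_ratio_min and sc > 0:
            effect = "green"
        elif abs(ratio - 1.0) <= brown_band or sc <= 0:
            effect = "brown"
        else:
            effect = "indeterminate"
    return TrendComparison(
        interval=tuple(interval),
        years=np.asarray(cm.index, dtype=int),
        city_mean=cm.to_numpy(),
        land_mean=lm.to_numpy(),
        slope_city=sc, slope_land=sl,
        intercept_city=ic, intercept_land=il,
        resid_sd_city=rc, resid_sd_land=rl,
        ratio=ratio, effect=effect,
    )
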