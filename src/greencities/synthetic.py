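"""Synthetic co-registered worlds with known ground truth.

Generates the four layer families the pipeline consumes — nighttime
lights, annual NDVI, Schreiber-consistent surface fluxes, and vertebrate
abundance/threatened counts — on a shared geographic grid, together with
a truth record sufficient to score every recovery target:

* cities are compact random blobs whose pixel areas follow a discrete
  power law (Zipf-like: many small cities, few large ones);
* NDVI evolves linearly in time with separate planted slopes for city and
  non-city pixels plus i.i.d. Gaussian residuals;
* fluxes satisfy E = P (1 - exp(-D)) and H = P D - E exactly, so
  state-space consistency checks are exact rather than approximate;
* species counts are Poisson in NDVI-dependent intensity, with threatened
  counts a binomial thinning whose probability follows a planted profile
  over NDVI bins (flat, U-shape, or step jump).

The default world is 200 x 200 cells of ~1 km near the equator over 32
years, a toy-scale analogue of the GIMMS-era record.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import numpy.ma as ma
from scipy import ndimage

from .grid import GridRaster, TimeRaster, pixel_area_km2

__all__ = [
    "SyntheticTruth",
    "make_equatorial_grid",
    "gen_lights",
    "gen_ndvi_clim",
    "gen_ndvi_series",
    "gen_fluxes",
    "gen_climate",
    "gen_species",
    "make_world",
]


@dataclasses.dataclass
class SyntheticTruth:
    """Planted parameters and generation logs for one synthetic world."""

    seed: int
    params: dict = dataclasses.field(default_factory=dict)

    def update(self, **kwargs) -> None:
        self.params.update(kwargs)


def make_equatorial_grid(ny: int = 200, nx: int = 200,
                         cell_deg: float = 0.009) -> tuple[np.ndarray, np.ndarray]:
    """Edges of a grid of ~1 km cells centered on the equator/prime meridian."""
    lat = cell_deg * (np.arange(ny + 1) - ny / 2)
    lon = cell_deg * (np.arange(nx + 1) - nx / 2)
    return lat, lon


# ---------------------------------------------------------------------------
# Nighttime lights
# ---------------------------------------------------------------------------

_N4 = ((1, 0), (-1, 0), (0, 1), (0, -1))


def _sample_powerlaw_sizes(rng, n: int, exponent: float, smax: int) -> np.ndarray:
    s = np.arange(1, smax + 1, dtype=float)
    pmf = s ** (-exponent)
    pmf /= pmf.sum()
    return rng.choice(np.arange(1, smax + 1), size=n, p=pmf)


def _grow_blob(rng, start: tuple[int, int], size: int, ny: int, nx: int) -> set:
    """Randomized dilation from a seed pixel to ~target pixel count."""
    members = {start}
    frontier = [(start[0] + dy, start[1] + dx) for dy, dx in _N4
                if 0 <= start[0] + dy < ny and 0 <= start[1] + dx < nx]
    while len(members) < size and frontier:
        k = int(rng.integers(len(frontier)))
        frontier[k], frontier[-1] = frontier[-1], frontier[k]
        px = frontier.pop()
        if px in members:
            continue
        members.add(px)
        for dy, dx in _N4:
            q = (px[0] + dy, px[1] + dx)
            if 0 <= q[0] < ny and 0 <= q[1] < nx and q not in members:
                frontier.append(q)
    return members


def gen_lights(
    lat_edges: np.ndarray,
    lon_edges: np.ndarray,
    n_cities: int = 120,
    zipf_exponent: float = 2.0,
    seed: int = 0,
    max_city_px: int = 512,
    dim_background_frac: float = 0.05,
) -> tuple[GridRaster, SyntheticTruth]:
    """Integer DN raster in [0, 63] with planted power-law city blobs.

    City pixels draw DN uniformly from [12, 63]; the background is dark
    (DN 0) apart from a sprinkling of dim pixels below the threshold.
    Blobs that touch merge into one component; merges are recorded in the
    truth record.
    """
    if n_cities < 1:
        raise ValueError("n_cities must be at least 1")
    rng = np.random.default_rng(seed)
    ny, nx = len(lat_edges) - 1, len(lon_edges) - 1
    sizes = _sample_powerlaw_sizes(rng, n_cities, zipf_exponent, max_city_px)
    if sizes.sum() > 0.3 * ny * nx:
        raise ValueError(
            f"grid too small for {n_cities} cities totalling {sizes.sum()} px")
    dn = np.zeros((ny, nx), dtype=np.int64)
    centers = []
    for s in sizes:
        cy = int(rng.integers(ny))
        cx = int(rng.integers(nx))
        centers.append((cy, cx))
        for (py, px) in _grow_blob(rng, (cy, cx), int(s), ny, nx):
            dn[py, px] = int(rng.integers(12, 64))
    n_dim = int(dim_background_frac * ny * nx)
    if n_dim:
        flat = rng.choice(ny * nx, size=n_dim, replace=False)
        dark = dn.ravel()[flat] == 0
        dn.ravel()[flat[dark]] = rng.integers(1, 12, size=int(dark.sum()))
    labels, n_components = ndimage.label(
        dn >= 12, structure=ndimage.generate_binary_structure(2, 2))
    truth = SyntheticTruth(seed)
    truth.update(
        n_cities_requested=n_cities,
        zipf_exponent=zipf_exponent,
        target_sizes_px=sizes.tolist(),
        centers=centers,
        n_components=int(n_components),
        n_merges=int(n_cities - n_components),
    )
    light = GridRaster(dn, lat_edges, lon_edges, name="lights")
    return light, truth


# ---------------------------------------------------------------------------
# NDVI
# ---------------------------------------------------------------------------

def gen_ndvi_clim(lat_edges, lon_edges, seed: int = 0,
                  low: float = 0.0, high: float = 1.0) -> GridRaster:
    """Climatological NDVI field, uniform over [low, high).

    The uniform default makes every 0.1-wide NDVI bin equally populated,
    the flat-frequency profile against which planted bin structure is
    easiest to score.
    """
    rng = np.random.default_rng(seed)
    ny, nx = len(lat_edges) - 1, len(lon_edges) - 1
    vals = rng.uniform(low, high, size=(ny, nx))
    return GridRaster(vals, lat_edges, lon_edges, name="ndvi_clim")


def gen_ndvi_series(
    ndvi_clim: GridRaster,
    city_mask: np.ndarray,
    slope_city: float = 0.003,
    slope_land: float = 0.001,
    resid_sd: float = 0.01,
    years: Sequence[int] = tuple(range(1982, 2014)),
    seed: int = 0,
) -> tuple[TimeRaster, SyntheticTruth]:
    """Annual NDVI with planted per-stratum linear trends.

    NDVI(t) = clim + slope_stratum * (t - mean(t)) + eps with
    eps ~ Normal(0, resid_sd) i.i.d.; values are clipped to [-0.1, 1] and
    clip events logged in the truth record.  *slope_land* here is the
    slope applied to non-city pixels; the land-average (city + non-city)
    slope is their cover-weighted mixture.
    """
    rng = np.random.default_rng(seed)
    years = np.asarray(years, dtype=int)
    clim = np.asarray(ma.getdata(ndvi_clim.values), dtype=float)
    city = np.asarray(city_mask, bool)
    slope = np.where(city, slope_city, slope_land)
    tbar = years.mean()
    layers = []
    n_clipped = 0
    for year in years:
        field = clim + slope * (year - tbar) + rng.normal(0, resid_sd, clim.shape)
        clipped = (field < -0.1) | (field > 1.0)
        n_clipped += int(clipped.sum())
        layers.append(GridRaster(np.clip(field, -0.1, 1.0),
                                 ndvi_clim.lat_edges, ndvi_clim.lon_edges,
                                 name="ndvi"))
    truth = SyntheticTruth(seed)
    truth.update(slope_city=slope_city, slope_land=slope_land,
                 resid_sd=resid_sd, years=years.tolist(), n_clipped=n_clipped)
    return TimeRaster(years, layers), truth


# ---------------------------------------------------------------------------
# Fluxes
# ---------------------------------------------------------------------------

def gen_fluxes(precip: GridRaster, dryness: GridRaster
               ) -> tuple[GridRaster, GridRaster, GridRaster]:
    """Schreiber-consistent (E, H, P) fields from planted P and D.

    E = P (1 - exp(-D)) and H = P D - E, so every pixel satisfies both the
    energy balance N = E + H = P D and the equation of state exactly.
    """
    p = np.asarray(ma.getdata(precip.values), dtype=float)
    d = np.asarray(ma.getdata(dryness.values), dtype=float)
    if np.any(p <= 0) or np.any(d <= 0):
        raise ValueError("need P > 0 and D > 0 everywhere")
    e = p * -np.expm1(-d)
    h = p * d - e
    mk = precip.with_values
    return mk(e, name="evap"), mk(h, name="sensible"), mk(p, name="precip")


def gen_climate(lat_edges, lon_edges, seed: int = 0,
                p_range=(0.3, 3.0), d_range=(0.1, 4.0)
                ) -> tuple[GridRaster, GridRaster]:
    """Random precipitation (m/yr) and dryness-ratio fields."""
    rng = np.random.default_rng(seed)
    ny, nx = len(lat_edges) - 1, len(lon_edges) - 1
    p = GridRaster(rng.uniform(*p_range, size=(ny, nx)), lat_edges, lon_edges,
                   name="precip")
    d = GridRaster(rng.uniform(*d_range, size=(ny, nx)), lat_edges, lon_edges,
                   name="dryness")
    return p, d


# ---------------------------------------------------------------------------
# Species
# ---------------------------------------------------------------------------

def _profile_pi(profile: str, bin_width: float, argmin_bin: float,
                threshold_bin: float, pi_flat: float, pi_min: float,
                curvature: float, pi_low: float, pi_high: float) -> np.ndarray:
    nb = int(round(1.0 / bin_width))
    b = np.arange(nb, dtype=float)
    if profile == "flat":
        pi = np.full(nb, pi_flat)
    elif profile == "u_shape":
        b0 = argmin_bin / bin_width
        pi = pi_min + curvature * (b - b0) ** 2
    elif profile == "step_jump":
        b0 = threshold_bin / bin_width
        pi = np.where(b < b0, pi_low, pi_high)
    else:
        raise ValueError(f"unknown indicator profile {profile!r}")
    return np.clip(pi, 0.0, 1.0)


def gen_species(
    ndvi_clim: GridRaster,
    seed: int = 0,
    profile: str = "flat",
    bin_width: float = 0.1,
    argmin_bin: float = 0.3,
    threshold_bin: float = 0.4,
    pi_flat: float = 0.1,
    pi_min: float = 0.02,
    curvature: float = 0.01,
    pi_low: float = 0.05,
    pi_high: float = 0.25,
    lam0: float = 20.0,
    lam1: float = 180.0,
) -> tuple[GridRaster, GridRaster, SyntheticTruth]:
    """Abundance and threatened-count rasters with a planted threat profile.

    abundance ~ Poisson(lam0 + lam1 * NDVI), monotone increasing in
    greenness; threatened ~ Binomial(abundance, pi(bin)) where pi follows
    the planted profile over half-open NDVI bins:

    - ``flat``: pi constant (``pi_flat``);
    - ``u_shape``: pi quadratic in bin index with its minimum at the bin
      starting at ``argmin_bin``;
    - ``step_jump``: pi_low below the bin starting at ``threshold_bin``,
      pi_high from there on.
    """
    rng = np.random.default_rng(seed)
    ndvi = np.asarray(ma.getdata(ndvi_clim.values), dtype=float)
    lam = lam0 + lam1 * np.clip(ndvi, 0.0, 1.0)
    abundance = rng.poisson(lam)
    pi_bins = _profile_pi(profile, bin_width, argmin_bin, threshold_bin,
                          pi_flat, pi_min, curvature, pi_low, pi_high)
    nb = pi_bins.size
    idx = np.clip((np.clip(ndvi, 0.0, 1.0) / bin_width).astype(int), 0, nb - 1)
    threatened = rng.binomial(abundance, pi_bins[idx])
    truth = SyntheticTruth(seed)
    truth.update(profile=profile, pi_bins=pi_bins.tolist(),
                 argmin_bin=argmin_bin, threshold_bin=threshold_bin,
                 lam0=lam0, lam1=lam1)
    mk = ndvi_clim.with_values
    return (mk(abundance, name="abundance"),
            mk(threatened, name="threatened"), truth)


# ---------------------------------------------------------------------------
# Composed worlds
# ---------------------------------------------------------------------------

#: per-regime planted parameters: (slope_city, slope_land, profile)
REGIMES = {
    "china": dict(slope_city=0.003, slope_land=0.001, profile="u_shape"),
    "america": dict(slope_city=0.002, slope_land=0.002, profile="step_jump"),
}


def make_world(
    seed: int = 0,
    ny: int = 200,
    nx: int = 200,
    n_years: int = 32,
    n_cities: int = 120,
    zipf_exponent: float = 2.0,
    regime: str = "china",
    resid_sd: float = 0.01,
) -> dict:
    """Generate a fully co-registered synthetic world for one regime.

    Returns a dict with the layers (lights, ndvi_clim, ndvi_series, evap,
    sensible, precip, abundance, threatened, areas), the city pixel mask
    derived from the planted lights, and a combined truth record.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; choose from {sorted(REGIMES)}")
    cfg = REGIMES[regime]
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=5)]
    lat_edges, lon_edges = make_equatorial_grid(ny, nx)
    lights, truth_l = gen_lights(lat_edges, lon_edges, n_cities=n_cities,
                                 zipf_exponent=zipf_exponent, seed=sub[0])
    city_mask = np.asarray(ma.getdata(lights.values)) >= 12
    ndvi_clim = gen_ndvi_clim(lat_edges, lon_edges, seed=sub[1])
    years = tuple(range(2013 - n_years + 1, 2013 + 1))
    series, truth_n = gen_ndvi_series(
        ndvi_clim, city_mask, slope_city=cfg["slope_city"],
        slope_land=cfg["slope_land"], resid_sd=resid_sd, years=years,
        seed=sub[2])
    precip, dryness = gen_climate(lat_edges, lon_edges, seed=sub[3])
    evap, sensible, precip = gen_fluxes(precip, dryness)
    abundance, threatened, truth_s = gen_species(
        ndvi_clim, seed=sub[4], profile=cfg["profile"])
    areas = pixel_area_km2(lights)
    truth = SyntheticTruth(seed)
    truth.update(regime=regime, lights=truth_l.params, ndvi=truth_n.params,
                 species=truth_s.params, dryness_field="uniform(0.1, 4.0)")
    return {
        "lights": lights,
        "ndvi_clim": ndvi_clim,
        "ndvi_series": series,
        "evap": evap,
        "sensible": sensible,
        "precip": precip,
        "dryness": dryness,
        "abundance": abundance,
        "threatened": threatened,
        "areas": areas,
        "city_mask": city_mask,
        "land_mask": np.ones_like(city_mask, dtype=bool),
        "truth": truth,
    }
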