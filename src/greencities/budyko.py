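"""Eco-hydrological (E, H) state space in the Budyko framework.

The land surface partitions net radiation N into evapotranspiration E and
sensible heat flux H (all expressed in water equivalents, m/yr), so that
N = E + H.  Relating water demand N to water supply (precipitation P)
gives the dryness ratio D = N / P, and Schreiber's equation of state
E/P = 1 - exp(-D) closes the climatological rainfall-runoff chain.  With
these, isolines of constant P and constant D can be drawn in the plane
spanned by E and H (Stephenson's diagram), and any gridded quantity can be
embedded there as a weighted 2-D frequency distribution.

Units: energy fluxes arrive as half-day integrals (J m^-2 per 12 h) and
are converted to water equivalents via the latent heat of condensation
L = 0.25e7 J/kg at 0 degrees C, i.e. one unit of input flux corresponds to
2.920e-7 m/yr of evaporated water.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import numpy.ma as ma
from scipy import ndimage

from .grid import GridRaster

__all__ = [
    "LATENT_HEAT_J_PER_KG",
    "ENERGY_TO_WATER_M_PER_YR",
    "DRYNESS_BOUNDS",
    "StateSpaceHistogram",
    "energy_to_water_equivalent",
    "schreiber_ratio",
    "precipitation_isoline",
    "dryness_isoline",
    "classify_dryness_regime",
    "embed",
    "smooth",
]

LATENT_HEAT_J_PER_KG = 0.25e7     # latent heat of condensation at 0 C
WATER_DENSITY_KG_PER_M3 = 1000.0
#: m/yr of water per (J m^-2 per 12 h): two half-days x 365 days / (L * rho)
ENERGY_TO_WATER_M_PER_YR = 2 * 365 / (LATENT_HEAT_J_PER_KG * WATER_DENSITY_KG_PER_M3)

#: geobotanic regime boundaries on the dryness ratio D
DRYNESS_BOUNDS = (1.0 / 3.0, 1.0, 2.0, 3.0)
DRYNESS_REGIMES = ("tundra", "forest", "steppe_savanna", "semi_desert", "desert")


def energy_to_water_equivalent(flux):
    """Convert an energy flux in J m^-2 (12 h)^-1 to water-equivalent m/yr.

    One unit of input yields 2.920e-7 m/yr.
    """
    return np.asarray(flux, dtype=float) * ENERGY_TO_WATER_M_PER_YR


def schreiber_ratio(dryness):
    """Evaporative fraction E/P = 1 - exp(-D) under Schreiber's equation.

    Strictly increasing in D, bounded in [0, 1).
    """
    d = np.asarray(dryness, dtype=float)
    if np.any(d < 0):
        raise ValueError("dryness ratio D must be non-negative")
    return -np.expm1(-d)


def precipitation_isoline(evap, precip):
    """Sensible heat on the isoline of constant precipitation.

    H = -P ln(1 - E/P) - E, the locus of (E, H) points sharing supply P
    under Schreiber's equation.  Requires 0 <= E < P.
    """
    e = np.asarray(evap, dtype=float)
    p = np.asarray(precip, dtype=float)
    if np.any(e < 0) or np.any(p <= 0):
        raise ValueError("need E >= 0 and P > 0")
    if np.any(e >= p):
        raise ValueError("E must be strictly below P (Schreiber asymptote)")
    return -p * np.log1p(-e / p) - e


def dryness_isoline(sensible, dryness):
    """Evapotranspiration on the isoline of constant dryness D.

    E = H (1 - exp(-D)) / (D - 1 + exp(-D)); rays of constant climate
    aridity through the (E, H) plane.  Requires H >= 0 and D large enough
    that the denominator (~ D^2/2 for small D) does not underflow.
    """
    h = np.asarray(sensible, dtype=float)
    d = np.asarray(dryness, dtype=float)
    if np.any(h < 0):
        raise ValueError("sensible heat H must be non-negative")
    if np.any(d <= 0):
        raise ValueError("dryness ratio D must be positive")
    denom = d - 1 + np.exp(-d)
    if np.any(denom < 1e-12):
        raise ValueError(
            "dryness ratio too small: D - 1 + exp(-D) underflows; the isoline "
            "degenerates toward the H = 0 axis as D -> 0"
        )
    return h * -np.expm1(-d) / denom


def classify_dryness_regime(dryness):
    """Geobotanic climate regime for a dryness ratio D.

    Half-open intervals [lo, hi): tundra [0, 1/3), forest [1/3, 1),
    steppe_savanna [1, 2), semi_desert [2, 3), desert [3, inf).  Boundary
    values belong to the drier (upper) class.
    """
    d = np.asarray(dryness, dtype=float)
    if np.any(d < 0):
        raise ValueError("dryness ratio D must be non-negative")
    idx = np.searchsorted(np.asarray(DRYNESS_BOUNDS), d, side="right")
    out = np.asarray(DRYNESS_REGIMES, dtype=object)[idx]
    if np.isscalar(dryness) or np.ndim(dryness) == 0:
        return str(out)
    return out


@dataclasses.dataclass
class StateSpaceHistogram:
    """Weighted 2-D frequency over (E, H) bins."""

    e_edges: np.ndarray
    h_edges: np.ndarray
    weights: np.ndarray          # shape (n_e_bins, n_h_bins)
    n_embedded: int = 0
    n_excluded: int = 0          # invalid flux or out-of-range pixels

    @property
    def total_mass(self) -> float:
        return float(self.weights.sum())

    def to_frame(self):
        """Long-format export with one row per (E, H) bin."""
        import pandas as pd

        ne, nh = self.weights.shape
        ei, hi = np.meshgrid(np.arange(ne), np.arange(nh), indexing="ij")
        return pd.DataFrame({
            "E_lo": self.e_edges[ei.ravel()],
            "E_hi": self.e_edges[ei.ravel() + 1],
            "H_lo": self.h_edges[hi.ravel()],
            "H_hi": self.h_edges[hi.ravel() + 1],
            "weight": self.weights.ravel(),
        })


def embed(
    evap: GridRaster,
    sensible: GridRaster,
    weights: GridRaster | None = None,
    bins: int | tuple = 50,
) -> StateSpaceHistogram:
    """Embed a layer in (E, H) state space as a weighted 2-D histogram.

    Each valid pixel contributes its weight (1 for number density) to the
    bin containing its (E, H) pair.  Pixels with E <= 0, H < 0, masked
    fluxes or masked weights are excluded and counted in ``n_excluded``;
    the state-space equations require non-negative fluxes.

    *bins* may be an integer (per axis, edges spanning the valid data) or
    a pair of explicit edge arrays ``(e_edges, h_edges)``; with explicit
    edges, out-of-range pixels are also excluded and counted.
    """
    if not evap.same_grid(sensible):
        raise ValueError("E and H rasters are not co-registered")
    e = evap.filled_values(np.nan).ravel()
    h = sensible.filled_values(np.nan).ravel()
    if weights is not None:
        if not weights.same_grid(evap):
            raise ValueError("weight raster is not co-registered with fluxes")
        w = weights.filled_values(np.nan).ravel()
    else:
        w = np.ones_like(e)
    valid = np.isfinite(e) & np.isfinite(h) & np.isfinite(w) & (e > 0) & (h >= 0)
    n_bad = int((~valid).sum())
    e, h, w = e[valid], h[valid], w[valid]
    if e.size == 0:
        import warnings

        warnings.warn("no valid pixels to embed; returning empty histogram",
                      stacklevel=2)
        edges = np.linspace(0, 1, 2)
        return StateSpaceHistogram(edges, edges, np.zeros((1, 1)), 0, n_bad)
    if isinstance(bins, int):
        e_edges = np.linspace(e.min(), e.max() + 1e-12, bins + 1)
        h_edges = np.linspace(h.min(), h.max() + 1e-12, bins + 1)
    else:
        e_edges = np.asarray(bins[0], dtype=float)
        h_edges = np.asarray(bins[1], dtype=float)
    hist, _, _ = np.histogram2d(e, h, bins=(e_edges, h_edges), weights=w)
    in_range = ((e >= e_edges[0]) & (e <= e_edges[-1])
                & (h >= h_edges[0]) & (h <= h_edges[-1]))
    # histogram2d drops out-of-range samples; account for them explicitly
    n_out = int((~in_range).sum())
    return StateSpaceHistogram(e_edges, h_edges, hist,
                               n_embedded=int(in_range.sum()),
                               n_excluded=n_bad + n_out)


def smooth(hist: StateSpaceHistogram, bandwidth: float = 1.0) -> StateSpaceHistogram:
    """Gaussian-smooth a state-space histogram, conserving total mass.

    *bandwidth* is the kernel standard deviation in bin units; reflective
    boundaries keep mass inside the domain.  A bandwidth of 0 is the
    identity.
    """
    if bandwidth < 0:
        raise ValueError("bandwidth must be non-negative")
    if bandwidth == 0:
        return dataclasses.replace(hist, weights=hist.weights.copy())
    sm = ndimage.gaussian_filter(hist.weights, sigma=bandwidth, mode="reflect")
    return dataclasses.replace(hist, weights=sm)
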