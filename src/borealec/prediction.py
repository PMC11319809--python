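"""Warming-driven change maps and the CO2-fertilization comparison term.

A constrained feedback factor gamma (%/degC) translates a warming map
DeltaT into a predicted percentage change per cell via the compounded form
((1 + gamma/100)^DeltaT - 1) * 100, equivalent to e^{b DeltaT} with
b = ln(1 + gamma/100); a linear gamma * DeltaT option exists for small-
warming comparison.  The CO2 term scales a per-doubling fertilization
factor beta linearly with the fractional CO2 increase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .emergent_constraint import ConstrainedEstimate
from .gridded_io import cell_weights


class RegionError(ValueError):
    pass


@dataclass
class ChangeMap:
    """Predicted per-cell % change and its gamma-propagated uncertainty."""

    change: xr.DataArray  # %
    sigma: xr.DataArray  # %
    delta_t: xr.DataArray  # degC
    variable: str
    gamma: float  # %/degC
    gamma_sd: float


def predict_change_map(
    gamma: ConstrainedEstimate | tuple[float, float],
    delta_t: xr.DataArray,
    variable: str = "LAI",
    linear: bool = False,
) -> ChangeMap:
    """Cellwise predicted % change from a warming map.

    Compounded by default: change = ((1 + gamma/100)^DeltaT - 1) * 100,
    monotone in DeltaT for gamma > 0 and zero at DeltaT = 0.  Uncertainty
    is propagated from sigma_gamma by the delta method.
    """
    if isinstance(gamma, ConstrainedEstimate):
        g, sg = gamma.mean, gamma.sd
    else:
        g, sg = float(gamma[0]), float(gamma[1])
    dt = delta_t.astype(float)
    r = 1.0 + g / 100.0
    if r <= 0:
        raise ValueError("gamma must exceed -100 %/degC")
    if linear:
        change = g * dt
        dchange_dg = dt
    else:
        change = (r**dt - 1.0) * 100.0
        dchange_dg = dt * r ** (dt - 1.0)
    sigma = np.abs(dchange_dg) * sg
    return ChangeMap(
        change=change.rename("change"),
        sigma=sigma.rename("sigma"),
        delta_t=delta_t,
        variable=variable,
        gamma=g,
        gamma_sd=sg,
    )


def regional_mean_change(
    cmap: ChangeMap, region: xr.DataArray | np.ndarray | None = None
) -> tuple[float, float]:
    """Area-weighted regional mean % change and its uncertainty.

    The gamma error is fully correlated across cells, so the regional sigma
    is the area-weighted mean of the cellwise sigmas, not reduced by
    averaging.
    """
    change = np.asarray(cmap.change.values, dtype=float)
    sigma = np.asarray(cmap.sigma.values, dtype=float)
    lat = np.asarray(cmap.change["lat"].values, dtype=float)
    w = np.broadcast_to(cell_weights(lat)[:, None], change.shape).copy()
    if region is not None:
        w = w * np.asarray(getattr(region, "values", region), dtype=bool)
    w = np.where(np.isfinite(change), w, 0.0)
    if w.sum() == 0:
        raise RegionError("region contains no valid cells")
    mean = float((w * np.where(w > 0, change, 0.0)).sum() / w.sum())
    sig = float((w * np.where(w > 0, sigma, 0.0)).sum() / w.sum())
    return mean, sig


def longitude_region_masks(
    lat: np.ndarray, lon: np.ndarray, eurasia_bounds: tuple[float, float] = (15.0, 190.0)
) -> dict[str, xr.DataArray]:
    """Continental masks split by longitude (degrees east, 0-360).

    Default: Eurasia from 15 E eastward across the date line to 170 W;
    North America the rest.
    """
    lon360 = np.mod(np.asarray(lon, dtype=float), 360.0)
    lo, hi = eurasia_bounds
    eurasia_1d = (lon360 >= lo) & (lon360 < hi)
    shape = (np.asarray(lat).size, lon360.size)
    eurasia = np.broadcast_to(eurasia_1d[None, :], shape)
    coords = {"lat": np.asarray(lat, dtype=float), "lon": np.asarray(lon, dtype=float)}
    return {
        "eurasia": xr.DataArray(eurasia, coords=coords, dims=("lat", "lon")),
        "north_america": xr.DataArray(~eurasia, coords=coords, dims=("lat", "lon")),
    }


@dataclass
class CO2FertilizationParams:
    """Per-doubling fertilization factor and the CO2 interval to scale it to."""

    beta_2x: float  # % GPP increase per CO2 doubling
    sigma_beta: float  # %
    co2_ref: float  # ppm
    co2_new: float  # ppm

    def __post_init__(self) -> None:
        if self.co2_ref <= 0:
            raise ValueError("co2_ref must be positive")

    @property
    def delta_co2(self) -> float:
        return self.co2_new - self.co2_ref


def co2_fertilization_change(params: CO2FertilizationParams) -> tuple[float, float]:
    """GPP % change (and sigma) from the CO2 increase, linear sub-doubling
    scaling: beta_2x * (co2_new - co2_ref) / co2_ref.

    Display convention is one decimal place; full precision is returned.
    """
    frac = params.delta_co2 / params.co2_ref
    return params.beta_2x * frac, params.sigma_beta * frac
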