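"""Gridded I/O: CF-style NetCDF read/write, block-mean coarsening, masks.

All analysis runs on an area-weighted coarse grid (default 4 deg x 5 deg) to
reduce sampling error; coarsening is strict block averaging, never
interpolation.  Latitude weights are cos(lat) at cell centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .containers import MONTHS_PER_YEAR, VARIABLE_UNITS, ScenarioRun

REQUIRED_VARIABLES = ("gpp", "lai", "tas", "treecover")
OPTIONAL_VARIABLES = ("par",)

_KELVIN_UNITS = {"k", "kelvin", "degk"}
_CELSIUS_UNITS = {"degc", "c", "celsius", "deg_c"}


class GriddedIOError(ValueError):
    pass


class MissingVariableError(GriddedIOError):
    def __init__(self, name: str):
        super().__init__(f"required variable {name!r} missing from file")
        self.variable = name


class UnitError(GriddedIOError):
    def __init__(self, name: str, units: str):
        super().__init__(f"variable {name!r} has unsupported units {units!r}")
        self.variable = name


class CalendarError(GriddedIOError):
    pass


class RegridError(GriddedIOError):
    pass


def write_run(run: ScenarioRun, path) -> None:
    """Write a scenario run as CF-style NetCDF (classic format)."""
    run.data.to_netcdf(path, engine="scipy")


def read_run(path) -> ScenarioRun:
    """Read a scenario run, validating variables, units and calendar.

    Temperatures in Kelvin are converted to degC; missing variables and
    non-monthly calendars raise typed errors naming the offender.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    for name in REQUIRED_VARIABLES:
        if name not in ds:
            raise MissingVariableError(name)
    if ds.sizes.get("time", 0) % MONTHS_PER_YEAR:
        raise CalendarError(
            f"time length {ds.sizes.get('time', 0)} is not a whole number of "
            "12-month years; monthly calendar required"
        )
    for axis in ("lat", "lon"):
        coord = np.asarray(ds[axis].values)
        if not (np.all(np.diff(coord) > 0) or np.all(np.diff(coord) < 0)):
            raise GriddedIOError(f"coordinate {axis!r} is not strictly monotone")
    tas_units = str(ds["tas"].attrs.get("units", "degC")).lower()
    if tas_units in _KELVIN_UNITS:
        ds["tas"] = ds["tas"] - 273.15
        ds["tas"].attrs["units"] = VARIABLE_UNITS["tas"]
    elif tas_units not in _CELSIUS_UNITS:
        raise UnitError("tas", tas_units)
    return ScenarioRun(
        model_id=str(ds.attrs.get("model_id", "unknown")),
        scenario=str(ds.attrs.get("scenario", "S2")),
        data=ds,
        start_year=int(ds.attrs.get("start_year", 1901)),
    )


def cell_weights(lat: np.ndarray) -> np.ndarray:
    """Relative cell areas of a regular grid: cos(latitude of cell center)."""
    return np.cos(np.deg2rad(np.asarray(lat, dtype=float)))


def _uniform_spacing(coord: np.ndarray, axis: str) -> float:
    steps = np.diff(coord)
    if steps.size == 0:
        raise RegridError(f"axis {axis!r} has a single cell; cannot coarsen")
    if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
        raise RegridError(f"axis {axis!r} is not uniformly spaced")
    return float(abs(steps[0]))


def _block_factor(target: float, source: float, axis: str) -> int:
    ratio = target / source
    factor = round(ratio)
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise RegridError(
            f"target {axis} cell {target} deg is not an integer multiple of "
            f"source cell {source} deg"
        )
    return factor


def regrid_coarse(
    field: xr.DataArray,
    target_cell: tuple[float, float],
    min_valid_area: float = 0.5,
) -> xr.DataArray:
    """Area-weighted block mean onto a coarser grid.

    The target (dlat, dlon) must be integer multiples of the source spacing.
    A coarse cell is masked when less than ``min_valid_area`` of its source
    area is valid.
    """
    lat = np.asarray(field["lat"].values, dtype=float)
    lon = np.asarray(field["lon"].values, dtype=float)
    f_lat = _block_factor(target_cell[0], _uniform_spacing(lat, "lat"), "lat")
    f_lon = _block_factor(target_cell[1], _uniform_spacing(lon, "lon"), "lon")
    if lat.size % f_lat or lon.size % f_lon:
        raise RegridError(
            f"grid ({lat.size} x {lon.size}) not divisible into "
            f"{f_lat} x {f_lon} blocks"
        )
    if f_lat == 1 and f_lon == 1:
        return field.copy()

    data = np.asarray(field.transpose(..., "lat", "lon").values, dtype=float)
    lead = data.shape[:-2]
    nlat_c, nlon_c = lat.size // f_lat, lon.size // f_lon
    blocks = data.reshape(lead + (nlat_c, f_lat, nlon_c, f_lon))
    w = cell_weights(lat).reshape(nlat_c, f_lat)[:, :, None, None]
    valid = np.isfinite(blocks)
    wsum_valid = (w * valid).sum(axis=(-3, -1))
    wsum_total = (w * np.ones_like(blocks)).sum(axis=(-3, -1))
    with np.errstate(invalid="ignore"):
        mean = (w * np.where(valid, blocks, 0.0)).sum(axis=(-3, -1)) / wsum_valid
    mean = np.where(wsum_valid / wsum_total >= min_valid_area, mean, np.nan)

    coords = {
        name: field.coords[name]
        for name in field.dims
        if name not in ("lat", "lon")
    }
    coords["lat"] = lat.reshape(nlat_c, f_lat).mean(axis=1)
    coords["lon"] = lon.reshape(nlon_c, f_lon).mean(axis=1)
    dims = tuple(d for d in field.dims if d not in ("lat", "lon")) + ("lat", "lon")
    out = xr.DataArray(mean, coords=coords, dims=dims, name=field.name, attrs=dict(field.attrs))
    return out.transpose(*[d for d in field.dims])


def regrid_run(run: ScenarioRun, target_cell: tuple[float, float]) -> ScenarioRun:
    """Coarsen every variable of a run onto the analysis grid."""
    coarse = {name: regrid_coarse(run.data[name], target_cell) for name in run.data.data_vars}
    ds = xr.Dataset(coarse, attrs=dict(run.data.attrs))
    return ScenarioRun(run.model_id, run.scenario, ds, run.start_year)


@dataclass
class EligibilityMask:
    """Forest-cell eligibility: tree cover >= threshold and center > lat_min."""

    values: xr.DataArray  # boolean (lat, lon)
    threshold: float
    lat_min: float
    source: str = ""

    @property
    def n_cells(self) -> int:
        return int(self.values.sum())


def eligibility_mask(
    treecover: xr.DataArray,
    threshold: float = 0.4,
    lat_min: float = 50.0,
    source: str = "",
) -> EligibilityMask:
    cover = np.asarray(treecover.values, dtype=float)
    if np.nanmin(cover) < 0 or np.nanmax(cover) > 1:
        raise GriddedIOError("tree cover must be a fraction in [0, 1]")
    lat = np.asarray(treecover["lat"].values, dtype=float)
    ok = (cover >= threshold) & np.isfinite(cover) & (lat[:, None] > lat_min)
    values = xr.DataArray(
        ok, coords={"lat": treecover["lat"], "lon": treecover["lon"]}, dims=("lat", "lon")
    )
    return EligibilityMask(values=values, threshold=threshold, lat_min=lat_min, source=source)
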