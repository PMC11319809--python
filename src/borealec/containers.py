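"""Shared in-memory containers for gridded monthly fields.

A "run" is one factorial scenario of one model: an :class:`xarray.Dataset`
with monthly variables ``gpp``, ``lai``, ``tas``, ``par`` on
``(time, lat, lon)`` and a static ``treecover`` fraction on ``(lat, lon)``.
Time is an integer month index counted from January of ``start_year``;
invalid cells are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

MONTHS_PER_YEAR = 12

#: canonical variable names and units expected on disk and in memory
VARIABLE_UNITS = {
    "gpp": "gC m-2 d-1",
    "lai": "m2 m-2",
    "tas": "degC",
    "par": "W m-2",
    "treecover": "1",
}


@dataclass
class ScenarioRun:
    """One scenario (S1 or S2) of one model.

    S1 runs vary CO2 but repeat their first-20-year climate in every
    subsequent 20-year block; S2 runs vary both CO2 and climate, so the
    S2 - S1 difference isolates the climate effect.
    """

    model_id: str
    scenario: str  # "S1" | "S2"
    data: xr.Dataset
    start_year: int = 1901

    def __post_init__(self) -> None:
        if self.scenario not in ("S1", "S2", "S3"):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @property
    def n_years(self) -> int:
        n_months = self.data.sizes["time"]
        if n_months % MONTHS_PER_YEAR:
            raise ValueError("time length not divisible by 12")
        return n_months // MONTHS_PER_YEAR

    @property
    def end_year(self) -> int:
        return self.start_year + self.n_years - 1

    @property
    def lat(self) -> np.ndarray:
        return np.asarray(self.data["lat"].values)

    @property
    def lon(self) -> np.ndarray:
        return np.asarray(self.data["lon"].values)

    def field(self, name: str) -> xr.DataArray:
        if name not in self.data:
            raise KeyError(name)
        return self.data[name]
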