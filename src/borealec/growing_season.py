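"""Growing-season definition from the monthly productivity climatology.

For each cell and 20-year window, the growing season is the set of months
whose climatological GPP is strictly above 20% of the annual maximum.  A
cell's season is *valid* only if it has at least three months and a
well-defined spring and fall: at least one month strictly inside the
(20%, 80%)-of-maximum band on each side of the peak month.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import xarray as xr

from .containers import MONTHS_PER_YEAR


class GroupSpanError(ValueError):
    pass


class EmptyCellSetError(ValueError):
    pass


@dataclass(frozen=True)
class TemporalGroupSpec:
    """One 20-year window of the overlapping-group decomposition."""

    index: int  # 1-based
    start_year: int
    end_year: int

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1


def temporal_groups(
    start: int = 1901, end: int = 2010, length: int = 20, stride: int = 10
) -> list[TemporalGroupSpec]:
    """Overlapping windows: 1901-1920, 1911-1930, ..., 1991-2010 by default."""
    if end - start + 1 < length:
        raise GroupSpanError("span shorter than one window")
    groups = []
    y = start
    while y + length - 1 <= end:
        groups.append(TemporalGroupSpec(len(groups) + 1, y, y + length - 1))
        y += stride
    if groups[-1].end_year != end:
        raise GroupSpanError(
            f"span {start}-{end} does not tile into {length}-year windows at "
            f"{stride}-year stride"
        )
    return groups


@dataclass
class GrowingSeason:
    """Per-cell growing-season months and validity.

    ``months``/``spring``/``fall`` are boolean with month as the leading
    axis of length 12; trailing axes (if any) are spatial.  ``valid`` has
    the spatial shape only.
    """

    months: np.ndarray
    valid: np.ndarray
    spring: np.ndarray
    fall: np.ndarray
    threshold: float = 0.2
    band: tuple[float, float] = (0.2, 0.8)

    @property
    def length(self) -> np.ndarray:
        return self.months.sum(axis=0)

    def month_indices(self) -> list[int]:
        """Ordered month indices (0=Jan) of a single-cell season."""
        if self.months.ndim != 1:
            raise ValueError("month_indices is only defined for a single cell")
        return [int(i) for i in np.nonzero(self.months)[0]]


def _group_year_slice(group: TemporalGroupSpec, start_year: int, n_years: int) -> slice:
    y0 = group.start_year - start_year
    y1 = group.end_year - start_year + 1
    if y0 < 0 or y1 > n_years:
        raise GroupSpanError(
            f"group {group.start_year}-{group.end_year} outside field span "
            f"{start_year}-{start_year + n_years - 1}"
        )
    return slice(y0, y1)


def _as_year_month(values: np.ndarray) -> np.ndarray:
    if values.shape[0] % MONTHS_PER_YEAR:
        raise GroupSpanError("time axis not divisible by 12")
    return values.reshape((-1, MONTHS_PER_YEAR) + values.shape[1:])


def monthly_climatology(
    values: np.ndarray | xr.DataArray, group: TemporalGroupSpec, start_year: int
) -> np.ndarray:
    """Mean of each calendar month over the group's years; shape (12, ...)."""
    arr = np.asarray(getattr(values, "values", values), dtype=float)
    ym = _as_year_month(arr)
    sel = ym[_group_year_slice(group, start_year, ym.shape[0])]
    return sel.mean(axis=0)


def define_growing_season(
    clim: np.ndarray | Sequence[float],
    threshold: float = 0.2,
    band: tuple[float, float] = (0.2, 0.8),
    min_months: int = 3,
    min_limb_months: int = 1,
) -> GrowingSeason:
    """Growing season of a 12-month climatology (single cell or gridded).

    The threshold is relative ("larger than 20% of the maximum" read as
    strictly greater), so the season is invariant to rescaling.  The peak
    is the argmax, ties broken toward the earliest month.  ``min_limb_months``
    months must fall strictly inside the open band on each limb.
    """
    clim = np.asarray(clim, dtype=float)
    if clim.shape[0] != MONTHS_PER_YEAR:
        raise ValueError("climatology must have 12 months on the leading axis")
    if np.any(clim < 0):
        raise ValueError("climatology must be non-negative")
    mx = clim.max(axis=0)
    peak = clim.argmax(axis=0)
    months = clim > threshold * mx
    in_band = (clim > band[0] * mx) & (clim < band[1] * mx)
    midx_shape = (MONTHS_PER_YEAR,) + (1,) * (clim.ndim - 1)
    midx = np.arange(MONTHS_PER_YEAR).reshape(midx_shape)
    spring = in_band & (midx < peak)
    fall = in_band & (midx > peak)
    valid = (
        (mx > 0)
        & (months.sum(axis=0) >= min_months)
        & (spring.sum(axis=0) >= min_limb_months)
        & (fall.sum(axis=0) >= min_limb_months)
    )
    return GrowingSeason(
        months=months, valid=valid, spring=spring, fall=fall,
        threshold=threshold, band=band,
    )


def growing_season_mean(
    values: np.ndarray | xr.DataArray,
    gs: GrowingSeason,
    group: TemporalGroupSpec,
    start_year: int,
) -> np.ndarray:
    """Mean of a monthly field over GS months over the group's years.

    Cells with an invalid growing season are NaN.
    """
    arr = np.asarray(getattr(values, "values", values), dtype=float)
    ym = _as_year_month(arr)
    sel = ym[_group_year_slice(group, start_year, ym.shape[0])]
    monthly = sel.mean(axis=0)  # (12, ...)
    n = gs.months.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (monthly * gs.months).sum(axis=0) / n
    return np.where(gs.valid, mean, np.nan)


def persistent_valid_cells(
    valids: Iterable[np.ndarray], eligibility: np.ndarray | None = None
) -> np.ndarray:
    """Cells with a valid growing season in *every* group (and eligible).

    The same cell set is reused for all groups of a model; an empty result
    raises, since downstream fits would be degenerate.
    """
    out: np.ndarray | None = None
    for v in valids:
        v = np.asarray(v, dtype=bool)
        out = v.copy() if out is None else (out & v)
    if out is None:
        raise ValueError("no group validities supplied")
    if eligibility is not None:
        out &= np.asarray(getattr(eligibility, "values", eligibility), dtype=bool)
    if not out.any():
        raise EmptyCellSetError(
            "no cell keeps a valid growing season through all groups; "
            "revise the grid, tree-cover threshold, or GS thresholds"
        )
    return out
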