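"""Spatial exponential sensitivity of growing-season productivity to temperature.

The spatial relation across forest cells is modelled as C_i = a exp(d T_i),
fitted by ordinary least squares in log space (ln C = ln a + d T), and
summarised as the percentage change per degree, P = (e^d - 1) * 100.
GPP is decomposed into greenness and physiology by converting LAI to fPAR
with Beer's law (fPAR = 1 - e^{-k LAI}) and attributing the residual
coefficient d_GPP - d_fPAR to light-use efficiency (LUE), since
GPP = APAR x LUE is multiplicative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


class FitError(ValueError):
    pass


class CellSetMismatchError(ValueError):
    pass


@dataclass
class ExponentialFit:
    """Log-space OLS fit of C = a exp(d T) over forest cells."""

    a: float
    d: float  # 1/degC
    se_a: float
    se_d: float
    r2: float
    m: int  # cells used
    variable: str = "GPP"
    group: int | None = None
    model_id: str | None = None
    scenario: str | None = None
    n_dropped: int = 0  # non-positive / non-finite cells excluded

    @property
    def P(self) -> float:
        """Sensitivity, % change of C per degC."""
        return (math.exp(self.d) - 1.0) * 100.0

    def sensitivity(self) -> "SpatialSensitivity":
        return sensitivity_from_coefficient(
            self.d, self.se_d, variable=self.variable, model_id=self.model_id
        )


@dataclass
class SpatialSensitivity:
    P: float  # %/degC
    sigma_P: float  # %/degC
    d: float | None = None
    variable: str = "GPP"
    model_id: str | None = None


@dataclass
class ObservationalConstraint:
    """Combined multi-product observed spatial sensitivity (value, 1-sigma)."""

    P_obs: float
    sigma_obs: float
    products: list[tuple[float, float]] = field(default_factory=list)
    variable: str = "GPP"


def fit_exponential(
    C: np.ndarray,
    T: np.ndarray,
    variable: str = "GPP",
    group: int | None = None,
    model_id: str | None = None,
    scenario: str | None = None,
) -> ExponentialFit:
    """Fit ln C = ln a + d T across cells by OLS.

    Cells with non-positive or non-finite C (or non-finite T) are dropped
    and counted in ``n_dropped``.  Requires >= 3 usable cells and non-zero
    temperature variance.
    """
    C = np.asarray(C, dtype=float).ravel()
    T = np.asarray(T, dtype=float).ravel()
    if C.shape != T.shape:
        raise FitError("C and T must be paired arrays of equal length")
    keep = np.isfinite(C) & np.isfinite(T) & (C > 0)
    n_dropped = int(C.size - keep.sum())
    C, T = C[keep], T[keep]
    if C.size < 3:
        raise FitError(f"need >= 3 positive cells, got {C.size}")
    if np.ptp(T) == 0:
        raise FitError("zero temperature variance across cells")
    y = np.log(C)
    if np.ptp(y) == 0:
        # flat response: d = 0 exactly; no T-coupling
        return ExponentialFit(
            a=float(np.exp(y[0])), d=0.0, se_a=0.0, se_d=0.0, r2=0.0,
            m=int(C.size), variable=variable, group=group, model_id=model_id,
            scenario=scenario, n_dropped=n_dropped,
        )
    res = stats.linregress(T, y)
    a = math.exp(res.intercept)
    return ExponentialFit(
        a=a,
        d=float(res.slope),
        se_a=a * float(res.intercept_stderr),
        se_d=float(res.stderr),
        r2=float(res.rvalue) ** 2,
        m=int(C.size),
        variable=variable,
        group=group,
        model_id=model_id,
        scenario=scenario,
        n_dropped=n_dropped,
    )


def sensitivity_from_coefficient(
    d: float, se_d: float = 0.0, variable: str = "GPP", model_id: str | None = None
) -> SpatialSensitivity:
    """P = (e^d - 1) * 100, with delta-method sigma_P = 100 e^d se_d."""
    if not np.isfinite(d):
        raise FitError("coefficient d must be finite")
    return SpatialSensitivity(
        P=(math.exp(d) - 1.0) * 100.0,
        sigma_P=100.0 * math.exp(d) * se_d,
        d=d,
        variable=variable,
        model_id=model_id,
    )


def fpar_from_lai(lai, k: float = 0.5):
    """Beer's-law fPAR = 1 - exp(-k LAI); saturates toward 1."""
    return 1.0 - np.exp(-k * np.asarray(lai, dtype=float))


def lue_sensitivity(
    fit_gpp: ExponentialFit, fit_fpar: ExponentialFit
) -> SpatialSensitivity:
    """LUE sensitivity as the log-space difference d_GPP - d_fPAR.

    Uncertainty by quadrature of the two coefficient standard errors.
    A model whose greenness is more temperature-sensitive than its GPP has
    negative LUE sensitivity.
    """
    if fit_gpp.m != fit_fpar.m or fit_gpp.group != fit_fpar.group:
        raise CellSetMismatchError(
            "GPP and fPAR fits must use the same cells and group"
        )
    d = fit_gpp.d - fit_fpar.d
    se = math.hypot(fit_gpp.se_d, fit_fpar.se_d)
    s = sensitivity_from_coefficient(d, se, variable="LUE", model_id=fit_gpp.model_id)
    return s


def time_invariance(fits: Sequence[ExponentialFit | float]) -> tuple[float, float]:
    """Mean and sample sd of the per-group P values (time-invariance check)."""
    P = np.array([f.P if hasattr(f, "P") else float(f) for f in fits], dtype=float)
    if P.size < 2:
        raise FitError("need >= 2 groups for a time-invariance diagnostic")
    return float(P.mean()), float(P.std(ddof=1))


def filter_models(
    r2_by_model: Mapping[str, tuple[float | None, float | None]],
    r2_min: float = 0.1,
) -> list[str]:
    """Retain models with R^2 > r2_min for *either* the LAI-T or GPP-T relation.

    Values are (r2_lai, r2_gpp); None marks a missing monthly field, which
    excludes the model outright.
    """
    retained = []
    for model_id, (r2_lai, r2_gpp) in r2_by_model.items():
        if r2_lai is None or r2_gpp is None:
            continue
        if max(r2_lai, r2_gpp) > r2_min:
            retained.append(model_id)
    return retained


def combine_observed_products(
    products: Sequence[tuple[float, float]], variable: str = "GPP"
) -> ObservationalConstraint:
    """Combine per-product (P, sigma_fit) into a single constraint.

    P_obs is the unweighted product mean.  Its uncertainty combines, in
    quadrature, the standard error of the product mean (spread among
    products / sqrt(n)) and the mean per-product fitting sigma scaled by
    sqrt(n) -- both fitting noise and product disagreement contribute.
    """
    if len(products) < 1:
        raise ValueError("need at least one product")
    P = np.array([p for p, _ in products], dtype=float)
    sig = np.array([s for _, s in products], dtype=float)
    n = P.size
    spread = P.std(ddof=1) if n > 1 else 0.0
    sigma_obs = math.hypot(sig.mean() / math.sqrt(n), spread / math.sqrt(n))
    return ObservationalConstraint(
        P_obs=float(P.mean()),
        sigma_obs=float(sigma_obs),
        products=[(float(p), float(s)) for p, s in products],
        variable=variable,
    )
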