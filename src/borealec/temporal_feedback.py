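"""Temporal climate feedback factors from paired factorial runs.

For each 20-year group n (group 1 = reference), the climate-only change of
growing-season GPP or LAI is the spatial-mean log ratio

    delta_g(n) = mean_i [ ln(g_n,i / g_1,i)_S2 - ln(g_n,i / g_1,i)_S1 ]

so DeltaC(n) = exp(delta_g) is the geometric-mean S2/S1 ratio of ratios,
and DeltaT(n) is the spatial-mean GS-temperature change in S2.  A
zero-intercept fit of ln DeltaC on DeltaT (DeltaC = 1 at DeltaT = 0 by
construction) yields the coefficient b and the feedback factor

    gamma = (e^b - 1) * 100   [% per degC of warming].

Because overlapping 20-year windows share half their years, the group
points are serially correlated; the default standard error of b accounts
for the known overlap structure (``se_method="overlap"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np


class FeedbackFitError(ValueError):
    pass


@dataclass
class GroupChange:
    """Climate-only (or climate+CO2) change of group n relative to group 1."""

    n: int
    delta_g: float  # dimensionless log change
    delta_C: float  # exp(delta_g) > 0
    delta_T: float  # degC, S2 GS-temperature change
    scenario_mode: str = "S2_minus_S1"
    m_cells: int = 0
    n_dropped: int = 0
    se_delta_g: float = 0.0  # standard error of the spatial mean (cell spread)


@dataclass
class FeedbackFit:
    b: float  # 1/degC
    se_b: float
    gamma: float  # %/degC
    sigma_gamma: float
    model_id: str | None = None
    variable: str = "GPP"
    scenario_mode: str = "S2_minus_S1"
    n_groups: int = 0
    m_cells: int = 0


def group_change(
    gs_c_s1: np.ndarray,
    gs_c_s2: np.ndarray,
    gs_t_s2: np.ndarray,
    n: int,
    mode: str = "S2_minus_S1",
) -> GroupChange:
    """Change of group ``n`` (1-based, >= 2) relative to group 1.

    Inputs are per-cell growing-season means with shape (n_groups, m):
    ``gs_c_*`` the productivity state in each scenario and ``gs_t_s2`` the
    S2 GS temperature.  Cells with non-positive or non-finite state in any
    required group are dropped (logged in ``n_dropped``); in
    ``"S2_only"`` mode the S1 subtraction is omitted, so the change
    reflects climate plus CO2.
    """
    if mode not in ("S2_minus_S1", "S2_only"):
        raise ValueError(f"unknown scenario mode {mode!r}")
    if n < 2 or n > gs_c_s2.shape[0]:
        raise ValueError(f"group index {n} out of range")
    i = n - 1
    cols = [gs_c_s2[0], gs_c_s2[i]]
    if mode == "S2_minus_S1":
        cols += [gs_c_s1[0], gs_c_s1[i]]
    stack = np.stack(cols)
    keep = np.all(np.isfinite(stack) & (stack > 0), axis=0)
    keep &= np.isfinite(gs_t_s2[0]) & np.isfinite(gs_t_s2[i])
    n_dropped = int(keep.size - keep.sum())
    if not keep.any():
        raise FeedbackFitError(f"all cells dropped for group {n}")
    y_cells = np.log(gs_c_s2[i][keep] / gs_c_s2[0][keep])
    if mode == "S2_minus_S1":
        y_cells = y_cells - np.log(gs_c_s1[i][keep] / gs_c_s1[0][keep])
    m = int(keep.sum())
    delta_g = float(y_cells.mean())
    se = float(y_cells.std(ddof=1) / math.sqrt(m)) if m > 1 else 0.0
    delta_T = float(np.mean(gs_t_s2[i][keep] - gs_t_s2[0][keep]))
    return GroupChange(
        n=n, delta_g=delta_g, delta_C=math.exp(delta_g), delta_T=delta_T,
        scenario_mode=mode, m_cells=m, n_dropped=n_dropped, se_delta_g=se,
    )


def _overlap_correlation(ns: np.ndarray, window: int = 20, stride: int = 10) -> np.ndarray:
    """Correlation of group-change noise implied by window-year overlap."""
    sep = np.abs(ns[:, None] - ns[None, :]) * stride
    return np.clip(1.0 - sep / window, 0.0, None).astype(float)


def fit_gamma(
    changes: Sequence[GroupChange],
    model_id: str | None = None,
    variable: str = "GPP",
    se_method: str = "cells",
) -> FeedbackFit:
    """Zero-intercept OLS of ln DeltaC on DeltaT across groups n = 2..10.

    The intercept is fixed at zero because DeltaC = 1 at DeltaT = 0 by
    construction.  The default ``se_method="cells"`` propagates each
    group's spatial-mean standard error (from the cell-to-cell spread)
    through the fit, with the known window-overlap correlation between
    groups; ``"overlap"`` estimates a single noise scale from the fit
    residuals under the same correlation; ``"iid"`` is the naive
    residual-based estimator.
    """
    if len(changes) < 3:
        raise FeedbackFitError("need >= 3 group changes")
    x = np.array([c.delta_T for c in changes], dtype=float)
    y = np.array([c.delta_g for c in changes], dtype=float)
    ns = np.array([c.n for c in changes], dtype=float)
    if np.ptp(x) == 0:
        raise FeedbackFitError("degenerate delta_T: all group warmings equal")
    sxx = float(x @ x)
    b = float(x @ y) / sxx
    r = y - b * x
    k = x.size
    if se_method == "iid":
        sigma2 = float(r @ r) / (k - 1)
        var_b = sigma2 / sxx
    elif se_method == "overlap":
        C = _overlap_correlation(ns)
        H = np.outer(x, x) / sxx
        M = np.eye(k) - H
        denom = float(np.trace(M @ C @ M.T))
        sigma2 = float(r @ r) / denom if denom > 0 else 0.0
        var_b = sigma2 * float(x @ C @ x) / sxx**2
    elif se_method == "cells":
        s = np.array([c.se_delta_g for c in changes], dtype=float)
        cov = _overlap_correlation(ns) * np.outer(s, s)
        var_b = float(x @ cov @ x) / sxx**2
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    se_b = math.sqrt(max(var_b, 0.0))
    mode = changes[0].scenario_mode
    return FeedbackFit(
        b=b,
        se_b=se_b,
        gamma=(math.exp(b) - 1.0) * 100.0,
        sigma_gamma=100.0 * math.exp(b) * se_b,
        model_id=model_id,
        variable=variable,
        scenario_mode=mode,
        n_groups=k,
        m_cells=max(c.m_cells for c in changes),
    )


def predict_temporal_from_spatial(
    d: float, T_group1: np.ndarray, T_groupN: np.ndarray
) -> float:
    """Predicted total % change of C from warming, via the spatial coefficient.

    DeltaH = sum_i[e^{d T_n,i} - e^{d T_1,i}] / sum_i e^{d T_1,i} * 100,
    with groups 1 and N typically 1901-1920 and 1991-2010.
    """
    if not np.isfinite(d):
        raise ValueError("spatial coefficient d must be finite")
    T1 = np.asarray(T_group1, dtype=float).ravel()
    Tn = np.asarray(T_groupN, dtype=float).ravel()
    if T1.shape != Tn.shape:
        raise ValueError("temperature arrays must be paired")
    keep = np.isfinite(T1) & np.isfinite(Tn)
    e1 = np.exp(d * T1[keep])
    en = np.exp(d * Tn[keep])
    return float((en - e1).sum() / e1.sum() * 100.0)


def gamma_from_total_change(delta_h: float, mean_delta_t: float) -> float:
    """Convert a total % change over mean warming DeltaT to %/degC.

    Inverts (1 + gamma/100)^DeltaT = 1 + DeltaH/100, the per-degree rate
    consistent with the exponential feedback model.
    """
    if mean_delta_t == 0:
        raise ValueError("mean warming is zero; per-degree rate undefined")
    return ((1.0 + delta_h / 100.0) ** (1.0 / mean_delta_t) - 1.0) * 100.0
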