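"""Across-model emergent relation and observational conditioning.

The emergent-constraint construction: regress the per-model temporal
feedback factor gamma^G (%/degC) on the per-model spatial sensitivity P^G
(%/degC) with equal model weights, treat the residual spread as Gaussian
prediction noise, and condition on a Gaussian observation of the spatial
sensitivity:

    p(gamma | obs) = Int N(gamma; slope x + intercept, s^2)
                         N(x; P_obs, sigma_obs^2) dx

evaluated by numerical integration on a wide grid.  Because a convolution
of Gaussians is Gaussian, the closed form

    mean = slope P_obs + intercept,  sd = sqrt(slope^2 sigma_obs^2 + s^2)

serves as an independent cross-check of the numerical posterior.  The
unconstrained prior is the equal-weight Gaussian over the model gammas.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .spatial_sensitivity import ObservationalConstraint


class ConstraintError(ValueError):
    pass


@dataclass
class EmergentRelation:
    """Across-model linear relation gamma = slope * P + intercept."""

    slope: float
    intercept: float
    resid_sd: float  # rms residual, n-2 divisor
    r2: float
    n_models: int
    variable: str = "GPP"


@dataclass
class ConstrainedEstimate:
    """Posterior (observation-constrained) feedback factor."""

    mean: float  # %/degC
    sd: float
    prior_mean: float | None = None
    prior_sd: float | None = None
    uncertainty_reduction: float | None = None  # 1 - sd/prior_sd
    q10: float | None = None
    variable: str = "GPP"
    # density dump for plotting conditional-PDF analogues
    grid: np.ndarray | None = None
    pdf: np.ndarray | None = None


def fit_emergent_relation(
    P: Sequence[float], gamma: Sequence[float], variable: str = "GPP"
) -> EmergentRelation:
    """Equal-weight OLS of per-model gamma on per-model P (>= 3 models)."""
    P = np.asarray(P, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if P.shape != gamma.shape or P.ndim != 1:
        raise ConstraintError("P and gamma must be paired 1-D per-model arrays")
    n = P.size
    if n < 3:
        raise ConstraintError(f"need >= 3 models, got {n}")
    res = stats.linregress(P, gamma)
    resid = gamma - (res.slope * P + res.intercept)
    resid_sd = math.sqrt(float(resid @ resid) / (n - 2))
    return EmergentRelation(
        slope=float(res.slope),
        intercept=float(res.intercept),
        resid_sd=resid_sd,
        r2=float(res.rvalue) ** 2,
        n_models=n,
        variable=variable,
    )


def prior_pdf(gamma: Sequence[float]) -> tuple[float, float]:
    """Equal-weight Gaussian prior over model gammas: (mean, sample sd)."""
    gamma = np.asarray(gamma, dtype=float)
    if gamma.size < 2:
        raise ConstraintError("need >= 2 models for a prior")
    sd = float(gamma.std(ddof=1))
    if sd == 0:
        warnings.warn("degenerate prior: all model gammas identical", stacklevel=2)
    return float(gamma.mean()), sd


def closed_form_posterior(
    rel: EmergentRelation, obs: ObservationalConstraint
) -> tuple[float, float]:
    """Gaussian-convolution result used as the numerical oracle's cross-check."""
    mean = rel.slope * obs.P_obs + rel.intercept
    sd = math.hypot(rel.slope * obs.sigma_obs, rel.resid_sd)
    return float(mean), float(sd)


def constrain(
    rel: EmergentRelation,
    obs: ObservationalConstraint,
    prior: tuple[float, float] | None = None,
    n_grid: int = 1601,
    span: float = 8.0,
    keep_density: bool = False,
) -> ConstrainedEstimate:
    """Condition the emergent relation on the observed spatial sensitivity.

    The posterior density is computed by numerical integration over the
    observation's Gaussian; the Gaussian closed form is exact here and is
    used when either spread is (numerically) zero.
    """
    for name, value in (("slope", rel.slope), ("intercept", rel.intercept),
                        ("resid_sd", rel.resid_sd), ("P_obs", obs.P_obs),
                        ("sigma_obs", obs.sigma_obs)):
        if not np.isfinite(value):
            raise ConstraintError(f"non-finite {name}")
    if obs.sigma_obs < 0:
        raise ConstraintError("sigma_obs must be >= 0")
    cf_mean, cf_sd = closed_form_posterior(rel, obs)

    grid = pdf = None
    if rel.resid_sd > 0 and obs.sigma_obs > 0 and abs(rel.slope) > 0:
        x = np.linspace(
            obs.P_obs - span * obs.sigma_obs, obs.P_obs + span * obs.sigma_obs, n_grid
        )
        grid = np.linspace(cf_mean - span * cf_sd, cf_mean + span * cf_sd, n_grid)
        px = stats.norm.pdf(x, obs.P_obs, obs.sigma_obs)
        cond = stats.norm.pdf(
            grid[:, None], rel.slope * x[None, :] + rel.intercept, rel.resid_sd
        )
        pdf = np.trapezoid(cond * px[None, :], x, axis=1)
        norm = float(np.trapezoid(pdf, grid))
        pdf = pdf / norm
        mean = float(np.trapezoid(grid * pdf, grid))
        sd = math.sqrt(float(np.trapezoid((grid - mean) ** 2 * pdf, grid)))
    else:
        # a degenerate Gaussian convolution: closed form is exact
        mean, sd = cf_mean, cf_sd

    prior_mean = prior_sd = reduction = None
    if prior is not None:
        prior_mean, prior_sd = float(prior[0]), float(prior[1])
        if prior_sd > 0 and sd < prior_sd:
            reduction = 1.0 - sd / prior_sd
    return ConstrainedEstimate(
        mean=mean,
        sd=sd,
        prior_mean=prior_mean,
        prior_sd=prior_sd,
        uncertainty_reduction=reduction,
        q10=q10_from_gamma(mean),
        variable=rel.variable,
        grid=grid if keep_density else None,
        pdf=pdf if keep_density else None,
    )


def q10_from_gamma(gamma: float) -> float:
    """Fractional change per 10 degC warming on the printed %/degC scale.

    Defined as gamma * 10 / 100 (17.0 %/degC -> 1.7); uncertainties scale
    identically.  See :func:`q10_multiplicative` for the compounded
    convention.
    """
    if not np.isfinite(gamma):
        raise ConstraintError("gamma must be finite")
    return gamma / 10.0


def q10_multiplicative(d: float) -> float:
    """Conventional multiplicative Q10 of an exponential with rate d: e^{10d}."""
    return math.exp(10.0 * d)
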