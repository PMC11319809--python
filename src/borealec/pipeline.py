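"""End-to-end orchestration: runs -> growing season -> fits -> constraint.

Three steps mirror the analysis workflow: (1) per-model spatial exponential
fits of GS productivity on GS temperature per 20-year group; (2) per-model
temporal feedback factors from the S2-S1 group changes; (3) the
across-model emergent relation, conditioned on the observed spatial
sensitivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import growing_season as gs_mod
from . import spatial_sensitivity as ss
from . import temporal_feedback as tf
from .containers import ScenarioRun
from .emergent_constraint import (
    ConstrainedEstimate,
    EmergentRelation,
    constrain,
    fit_emergent_relation,
    prior_pdf,
)
from .gridded_io import eligibility_mask, regrid_run
from .spatial_sensitivity import ObservationalConstraint
from .synthetic_ensemble import EnsembleConfig, iter_ensemble

logger = logging.getLogger("borealec")

VARIABLES = ("GPP", "LAI", "FPAR", "LUE")
_FIELD_OF = {"GPP": "gpp", "LAI": "lai", "FPAR": "fpar"}


@dataclass
class ModelAnalysis:
    """Everything the ensemble stage needs from one model."""

    model_id: str
    m_cells: int
    spatial_fits: dict  # (variable, scenario) -> list[ExponentialFit] per group
    lue_P: dict  # scenario -> list of per-group LUE P values
    P_stats: dict  # (variable, scenario) -> (mean_P, sd_P) across groups
    d_mean: dict  # variable -> mean S2 coefficient over groups
    gamma: dict  # variable -> FeedbackFit (S2 - S1)
    gamma_s2only: dict  # variable -> FeedbackFit (S2 only: climate + CO2)
    predicted_dh: dict  # variable -> DeltaH % (group 1 -> last), from d_mean
    predicted_gamma: dict  # variable -> %/degC, DeltaH converted per degree
    mean_delta_t: float
    r2_gpp: float
    r2_lai: float


def _group_means(
    run: ScenarioRun,
    groups,
    gs_per_group,
    cells: np.ndarray,
    k_ext: float,
) -> dict[str, np.ndarray]:
    """GS means per group restricted to the persistent cells; (n_groups, m)."""
    out: dict[str, np.ndarray] = {}
    fields = {
        "gpp": run.data["gpp"].values,
        "lai": run.data["lai"].values,
        "tas": run.data["tas"].values,
        "fpar": ss.fpar_from_lai(run.data["lai"].values, k=k_ext),
    }
    if "par" in run.data:
        fields["par"] = run.data["par"].values
    for name, values in fields.items():
        rows = []
        for group, gs in zip(groups, gs_per_group):
            mean = gs_mod.growing_season_mean(values, gs, group, run.start_year)
            rows.append(mean[cells])
        out[name] = np.asarray(rows)
    return out


def analyze_pair(
    s1: ScenarioRun,
    s2: ScenarioRun,
    coarse_cell: tuple[float, float] | None = (4.0, 5.0),
    treecover_threshold: float = 0.4,
    lat_min: float = 50.0,
    k_ext: float = 0.5,
    gs_threshold: float = 0.2,
    gs_band: tuple[float, float] = (0.2, 0.8),
    min_limb_months: int = 1,
    se_method: str = "cells",
) -> ModelAnalysis:
    """Spatial and temporal sensitivity analysis for one model's S1/S2 pair."""
    if coarse_cell is not None:
        s1 = regrid_run(s1, coarse_cell)
        s2 = regrid_run(s2, coarse_cell)
    groups = gs_mod.temporal_groups(s2.start_year, s2.end_year)
    elig = eligibility_mask(
        s2.data["treecover"], threshold=treecover_threshold, lat_min=lat_min,
        source=f"treecover:{s2.model_id}",
    )

    # growing season per group per scenario, from the GPP climatology
    gs_by_scen = {}
    validities = []
    for run in (s1, s2):
        per_group = []
        for group in groups:
            clim = gs_mod.monthly_climatology(run.data["gpp"].values, group, run.start_year)
            season = gs_mod.define_growing_season(
                clim, threshold=gs_threshold, band=gs_band,
                min_limb_months=min_limb_months,
            )
            per_group.append(season)
            validities.append(season.valid)
        gs_by_scen[run.scenario] = per_group
    cells = gs_mod.persistent_valid_cells(validities, elig.values.values)
    m_cells = int(cells.sum())

    means_s1 = _group_means(s1, groups, gs_by_scen["S1"], cells, k_ext)
    means_s2 = _group_means(s2, groups, gs_by_scen["S2"], cells, k_ext)

    spatial_fits: dict = {}
    lue_P: dict = {}
    for scenario, means in (("S2", means_s2), ("S1", means_s1)):
        for var in ("GPP", "LAI", "FPAR"):
            key = _FIELD_OF[var]
            spatial_fits[(var, scenario)] = [
                ss.fit_exponential(
                    means[key][g], means["tas"][g], variable=var,
                    group=groups[g].index, model_id=s2.model_id, scenario=scenario,
                )
                for g in range(len(groups))
            ]
        lue_P[scenario] = [
            ss.lue_sensitivity(
                spatial_fits[("GPP", scenario)][g], spatial_fits[("FPAR", scenario)][g]
            ).P
            for g in range(len(groups))
        ]

    P_stats = {
        key: ss.time_invariance(fits) for key, fits in spatial_fits.items()
    }
    P_stats[("LUE", "S2")] = ss.time_invariance(lue_P["S2"])
    P_stats[("LUE", "S1")] = ss.time_invariance(lue_P["S1"])

    d_mean = {
        var: float(np.mean([f.d for f in spatial_fits[(var, "S2")]]))
        for var in ("GPP", "LAI", "FPAR")
    }

    gamma: dict = {}
    gamma_s2only: dict = {}
    for var in ("GPP", "LAI"):
        key = _FIELD_OF[var]
        changes = [
            tf.group_change(means_s1[key], means_s2[key], means_s2["tas"], n)
            for n in range(2, len(groups) + 1)
        ]
        gamma[var] = tf.fit_gamma(
            changes, model_id=s2.model_id, variable=var, se_method=se_method
        )
        changes_s2 = [
            tf.group_change(means_s1[key], means_s2[key], means_s2["tas"], n, mode="S2_only")
            for n in range(2, len(groups) + 1)
        ]
        gamma_s2only[var] = tf.fit_gamma(
            changes_s2, model_id=s2.model_id, variable=var, se_method=se_method
        )

    mean_delta_t = float(np.mean(means_s2["tas"][-1] - means_s2["tas"][0]))
    predicted_dh = {
        var: tf.predict_temporal_from_spatial(
            d_mean[var], means_s2["tas"][0], means_s2["tas"][-1]
        )
        for var in ("GPP", "LAI")
    }
    predicted_gamma = {
        var: tf.gamma_from_total_change(predicted_dh[var], mean_delta_t)
        for var in ("GPP", "LAI")
    }

    r2_gpp = float(np.mean([f.r2 for f in spatial_fits[("GPP", "S2")]]))
    r2_lai = float(np.mean([f.r2 for f in spatial_fits[("LAI", "S2")]]))
    logger.info(
        "model %s: %d cells, P_GPP=%.2f%%/degC, gamma_GPP=%.2f%%/degC",
        s2.model_id, m_cells, P_stats[("GPP", "S2")][0], gamma["GPP"].gamma,
    )
    return ModelAnalysis(
        model_id=s2.model_id,
        m_cells=m_cells,
        spatial_fits=spatial_fits,
        lue_P=lue_P,
        P_stats=P_stats,
        d_mean=d_mean,
        gamma=gamma,
        gamma_s2only=gamma_s2only,
        predicted_dh=predicted_dh,
        predicted_gamma=predicted_gamma,
        mean_delta_t=mean_delta_t,
        r2_gpp=r2_gpp,
        r2_lai=r2_lai,
    )


@dataclass
class EnsembleAnalysis:
    models: list[ModelAnalysis]
    retained: list[str]
    relation: dict = field(default_factory=dict)  # variable -> EmergentRelation
    prior: dict = field(default_factory=dict)  # variable -> (mean, sd)
    constrained: dict = field(default_factory=dict)  # variable -> ConstrainedEstimate
    obs: dict = field(default_factory=dict)  # variable -> ObservationalConstraint

    def model(self, model_id: str) -> ModelAnalysis:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(model_id)


def run_ensemble_analysis(
    config: EnsembleConfig | None = None,
    pairs: list[tuple[ScenarioRun, ScenarioRun]] | None = None,
    obs: dict[str, ObservationalConstraint] | None = None,
    coarse_cell: tuple[float, float] | None = (4.0, 5.0),
    r2_min: float = 0.1,
    **analyze_kwargs,
) -> EnsembleAnalysis:
    """Full three-step pipeline over a synthetic config or explicit run pairs."""
    if (config is None) == (pairs is None):
        raise ValueError("supply exactly one of config or pairs")
    source = iter_ensemble(config) if config is not None else pairs
    models = [
        analyze_pair(s1, s2, coarse_cell=coarse_cell, **analyze_kwargs)
        for s1, s2 in source
    ]
    retained = ss.filter_models(
        {m.model_id: (m.r2_lai, m.r2_gpp) for m in models}, r2_min=r2_min
    )
    result = EnsembleAnalysis(models=models, retained=retained, obs=dict(obs or {}))
    kept = [m for m in models if m.model_id in retained]
    for var in ("GPP", "LAI"):
        P = [m.P_stats[(var, "S2")][0] for m in kept]
        gam = [m.gamma[var].gamma for m in kept]
        if len(kept) >= 3:
            result.relation[var] = fit_emergent_relation(P, gam, variable=var)
            result.prior[var] = prior_pdf(gam)
            if obs and var in obs:
                result.constrained[var] = constrain(
                    result.relation[var], obs[var], prior=result.prior[var]
                )
    return result


def fits_table(analysis: EnsembleAnalysis) -> pd.DataFrame:
    """Per-model, per-group spatial-fit table (CSV-ready, fixed column order)."""
    rows = []
    for m in analysis.models:
        for (var, scenario), fits in m.spatial_fits.items():
            for f in fits:
                rows.append(
                    {
                        "model": m.model_id,
                        "scenario": scenario,
                        "group": f.group,
                        "variable": var,
                        "a": f.a,
                        "d": f.d,
                        "se_d": f.se_d,
                        "r2": f.r2,
                        "m": f.m,
                        "P": f.P,
                        "sigma_P": 100.0 * np.exp(f.d) * f.se_d,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["model", "scenario", "group", "variable", "a", "d", "se_d",
                 "r2", "m", "P", "sigma_P"],
    )


def gamma_table(analysis: EnsembleAnalysis) -> pd.DataFrame:
    """Per-model feedback-factor table, both scenario modes."""
    rows = []
    for m in analysis.models:
        for store in (m.gamma, m.gamma_s2only):
            for var, fit in store.items():
                rows.append(
                    {
                        "model": m.model_id,
                        "variable": var,
                        "mode": fit.scenario_mode,
                        "b": fit.b,
                        "se_b": fit.se_b,
                        "gamma": fit.gamma,
                        "sigma_gamma": fit.sigma_gamma,
                        "n_groups": fit.n_groups,
                        "m_cells": fit.m_cells,
                        "predicted_gamma": m.predicted_gamma.get(var),
                        "retained": m.model_id in analysis.retained,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["model", "variable", "mode", "b", "se_b", "gamma",
                 "sigma_gamma", "n_groups", "m_cells", "predicted_gamma",
                 "retained"],
    )


def summary_dict(analysis: EnsembleAnalysis) -> dict:
    """JSON-ready summary: relation, prior, posterior, Q10 per variable."""
    out: dict = {"retained_models": analysis.retained}
    for var in analysis.relation:
        rel = analysis.relation[var]
        block: dict = {
            "relation": {
                "slope": rel.slope, "intercept": rel.intercept,
                "resid_sd": rel.resid_sd, "r2": rel.r2, "n_models": rel.n_models,
            },
            "prior": {
                "mean": analysis.prior[var][0], "sd": analysis.prior[var][1],
            },
        }
        est = analysis.constrained.get(var)
        if est is not None:
            block["constrained"] = {
                "mean": est.mean,
                "sd": est.sd,
                "uncertainty_reduction": est.uncertainty_reduction,
                "q10": est.q10,
            }
        out[var] = block
    return out
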