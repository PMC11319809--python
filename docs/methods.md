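# Methods

## Analysis model

The pipeline estimates how strongly growing-season (GS) productivity over
high-latitude northern forests responds to temperature, in three steps.

**1. Spatial sensitivity.** For each model, scenario and 20-year window, the
relation between GS productivity `C` (GPP, LAI, or fPAR) and GS mean
temperature `T` across forest cells is modelled as `C = a·exp(d·T)` and
fitted by ordinary least squares in log space (`ln C = ln a + d·T`). The
exponential form reflects the kinetics of electron transport and
carboxylation below the thermal optimum — the study domain's GS temperatures
(roughly 5–18 °C) sit below that optimum, where a linear model would imply
negative productivity at temperatures still above freezing. The sensitivity
is reported as `P = (e^d − 1)·100` %/°C. fPAR is derived from LAI through
the Beer's-law approximation `fPAR = 1 − e^(−k·LAI)`; the sensitivity of
light-use efficiency (LUE) is the log-space difference `d_GPP − d_fPAR`,
because `GPP = APAR × LUE` is multiplicative. Models are retained only if
the mean R² of either the GPP–T or LAI–T relation exceeds 0.1 and both
monthly fields exist.

**2. Temporal feedback.** Paired factorial runs isolate the climate effect:
S1 varies CO₂ under a bit-identically repeating 1901–1920 climate, S2 varies
both. GS means are formed over ten 20-year windows at 10-year stride
(1901–1920 … 1991–2010). For window *n* the climate-only change is the
spatial mean log ratio `Δg(n) = mean_i[ln(g_n/g_1)_S2 − ln(g_n/g_1)_S1]`, so
`ΔC = e^Δg` is a geometric-mean ratio of ratios; `ΔT(n)` is the spatial mean
GS-temperature change in S2 (S1's window-mean climate is constant by
construction). A zero-intercept OLS of `ln ΔC` on `ΔT` gives `b` and the
feedback factor `γ = (e^b − 1)·100` %/°C. The intercept is pinned at zero
because `ΔC = 1` at `ΔT = 0` by construction; a free-intercept variant is a
one-line change in `fit_gamma` inputs but is deliberately not the default.
An `S2_only` mode omits the S1 subtraction and measures climate + CO₂
jointly.

**3. Emergent constraint.** Per-model temporal γ is regressed on per-model
spatial P with equal model weights. The unconstrained prior is the
equal-weight Gaussian over model γ values (mean, sample sd). The posterior
conditions the relation on an observed spatial sensitivity
`N(P_obs, σ_obs²)`:

    p(γ | obs) ∝ ∫ N(γ; slope·x + intercept, resid_sd²) N(x; P_obs, σ_obs²) dx

evaluated by trapezoidal integration on a ±8σ grid of 1601 points in each
dimension. Because the convolution of Gaussians is Gaussian, the closed form
(mean `slope·P_obs + intercept`, sd `sqrt(slope²σ_obs² + resid_sd²)`) is an
exact independent oracle; the numerical path is required to agree with it to
1e−6 and falls back to it only when a spread is exactly zero. Residual
spread is homoscedastic (`resid_sd`, n−2 divisor); the x-dependent
prediction-variance widening `s²(x) = resid_sd²(1 + 1/n + (x−x̄)²/Σ(xᵢ−x̄)²)`
was considered and left out of the default because with ≲10 models it is
dominated by estimation noise in the leverage term itself.

Constrained factors feed two prediction products: cellwise change maps
`((1 + γ/100)^ΔT − 1)·100` (compounded form, consistent with the exponential
feedback model; a linear `γ·ΔT` option exists for small-warming comparison)
with delta-method uncertainty, and the CO₂-fertilization comparison term
`β_2x · ΔCO₂/CO₂_ref` scaled linearly below a doubling.

## Growing-season definition

Per cell and window, the monthly GPP climatology defines the season: months
whose climatology is *strictly* greater than 20% of the annual maximum
("larger than 20%" read literally; ties at exactly 20% excluded, both
threshold and strictness configurable). A cell is valid only if the season
has ≥ 3 months and a well-defined spring and fall: at least one month
strictly inside the open (20%, 80%)-of-maximum band on each side of the
peak. The peak is the climatology argmax with ties broken toward the
earliest month. A reading in which each limb needs ≥ 3 band months is
selectable via `min_limb_months`. Cell membership is fixed per model by
intersecting validity over all windows and both scenarios with the
eligibility mask (tree cover ≥ 0.4 — inclusive — at cell centers north of
50° N, applied after coarsening); the season itself is re-derived per
window, so its length may drift.

## Synthetic ensemble

The generator emulates the statistical structure the estimators rely on, not
vegetation physiology. Each model is a pair `(a, d)` per variable plus
noise. A cell's GS temperature is `θ_i + w(y)`: `θ` spans 18 → 5 °C from the
southern to the northern edge (plus a ±0.75 °C longitudinal anomaly), and
`w` is linear warming (default 0.25 °C/decade in S2). Monthly productivity
is `a·exp(d·(θ_i + w(y)))·s_m·c(y)·ε`: `s` is a fixed unimodal monthly
template whose peak advances poleward and whose mean over the ground-truth
season is exactly 1; `c(y)` an optional CO₂ secular factor applied
identically to S1 and S2 (default off); `ε` multiplicative lognormal noise
with unit mean (default cv 0.15). Monthly temperature adds a
shape-following seasonal excursion `5·(s_m − 1)` °C whose GS mean is zero,
and optional additive Gaussian noise (default 0). PAR has a fixed seasonal
cycle plus a longitudinal "cloudiness" variation orthogonal to the
temperature field, so GS-PAR and GS-T are spatially decoupled. Tree cover
tapers from 0.85 to 0.05 across a treeline (default 76° N, 6° wide),
emulating models that declare the far north tundra.

Three structural choices make the noise-free pipeline *exact*, which the
tests exploit:

- linear-in-year warming gives every 20-year window the same within-window
  variance, so window means of `exp(d·w)` differ by exactly `exp(d·Δw̄)` —
  the zero-intercept temporal fit recovers `b = d` identically;
- the spatially uniform warming term is absorbed into the fit intercept, so
  the spatial regression recovers `d` identically in every window;
- template values are kept far from 20% of the maximum, so season
  membership never flips under climatological noise.

S1 tiles the first 240 months of the S2 climate bit-identically, and S1/S2
share the complete 1901–1920 state including the noise realisation — the
factorial difference therefore cancels the reference-window noise exactly.
The default domain is the 4° × 5° analysis grid itself (7 × 12 cells,
50–78° N, 72 eligible forest cells, 1901–2010); block coarsening (area
weights `cos(lat)`, coarse cells masked below 50% valid source area — an
explicit convention, since partial coverage is otherwise ambiguous) is
exercised by generating on finer grids. Generating directly at analysis
resolution avoids the log-space aggregation (Jensen) attenuation that block
averaging across a temperature gradient would otherwise introduce into the
ground truth.

What the generator does *not* emulate: spatially correlated noise,
disturbance and land-use history, model-structural diversity beyond
`(a, d, noise)`, precipitation limitation, bimodal (tropical) seasons, or
drifting seasonal timing. Passing tests therefore demonstrate estimator
correctness and calibration under the stated statistical structure, not
fidelity of any real model ensemble.

## Uncertainty estimation

- Spatial fits: OLS standard errors from `scipy.stats.linregress`;
  sensitivities propagate by the delta method (`σ_P = 100·e^d·se_d`).
- Temporal fits: overlapping windows share half their years, so the nine
  group changes are serially correlated (adjacent correlation ≈ 0.5, two
  strides apart ≈ 0). The default `se_method="cells"` estimates each
  group's standard error from the cell-to-cell spread of per-cell log
  ratios and propagates the known overlap correlation through the
  zero-intercept fit: `Var(b) = xᵀ(ρ ∘ ssᵀ)x / (xᵀx)²`. Monte-Carlo
  calibration on the generator gives 2σ coverage ≈ 96% (residual-based
  alternatives, `"overlap"` and `"iid"`, under-cover at ~88% and ~68%
  because nine correlated points leave too few degrees of freedom).
- Observed products combine as the unweighted mean, with
  `σ_obs = sqrt((mean σ_fit/√n)² + (sd of P/√n)²)` — fitting noise and
  product disagreement in quadrature. The combination formula is a package
  convention (configurable by combining products upstream); no standard one
  exists.
- Regional change uncertainties treat the γ error as fully correlated
  across cells (area-weighted mean of cellwise σ, no √N reduction).

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| GS threshold | 0.2 of max | – | suppresses low-signal shoulder months |
| spring/fall band | (0.2, 0.8) open | – | requires a resolved rise and fall |
| tree-cover threshold | 0.4 (inclusive) | fraction | excludes grass/cropland-dominated cells |
| analysis grid | 4° × 5° | degrees | reduces sampling error; block mean only |
| Beer's-law k | 0.5 | – | canonical boreal extinction coefficient; fPAR sensitivities are k-covariant |
| windows | 20 yr, 10-yr stride | – | matches the repeating-climate block; 10 windows |
| warming rate | 0.25 | °C/decade | high-latitude historical magnitude |
| noise cv | 0.15 | – | keeps group-mean noise at the few-percent level |
| R² filter | > 0.1 | – | drops temperature-decoupled models |
| Q10 | γ/10 | – | printed-scale convention; `q10_multiplicative` gives `e^{10d}` |

## Numerical choices and degenerate inputs

Cells with non-positive productivity are dropped per fit and counted, never
imputed; a window in which *all* cells drop is an error. Fits require ≥ 3
cells and non-zero temperature variance. A perfectly flat response returns
`d = 0` with `R² = 0` (no temperature coupling) rather than an undefined
ratio. All-zero climatologies are invalid seasons, not errors. The
posterior density integrates to 1 within 1e−8 on its grid; degenerate
(zero-spread) constraints short-circuit to the exact closed form. Seeds
propagate through `numpy.random.SeedSequence.spawn`, one child per model,
so single models can be regenerated independently and runs are bit-identical
across processes.

## Problem sizes

Default study conditions: 8 models, 110 years, 7 × 12-cell domain with 72
eligible forest cells, ten windows. The stochastic validation uses 100
pipeline replicates (constrained recovery of a true γ* = 17 %/°C against
four synthetic products), 200 replicates for temporal-fit coverage, and
1000 for spatial-fit coverage; these sizes put the Monte-Carlo error on a
coverage estimate near one percentage point.

## Known limitations

The emergent-constraint variance formula ignores uncertainty in the fitted
slope/intercept themselves (standard in the construction, but optimistic
for small ensembles). The S2−S1 cancellation of a nonzero common CO₂
factor is exact only up to the interaction between the secular factor and
the repeating-climate windows (relative error ~1e−3 at the default growth
rate). Regional masks use a simple longitude split (Eurasia 15° E → 170° W)
rather than coastlines. The reader should treat the synthetic-ensemble
recovery results as validation of the statistical machinery, not as
evidence about any real model ensemble.
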