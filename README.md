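# borealec

Emergent constraint on the temperature sensitivity of photosynthesis and
greenness over high-latitude northern forests (HLNF).

## The scientific problem

Warming and rising CO₂ both enhance plant growth north of 50° N, and
disentangling the two from observations alone is hard. Terrestrial
biosphere model ensembles disagree widely on the *photosynthesis–climate
feedback factor* γ — the percentage change of growing-season gross primary
productivity (GPP) or leaf area index (LAI) per degree of warming. But a
quantity the models *do* expose, and that satellites can measure, is the
**spatial** sensitivity of growing-season productivity to temperature: across
forest cells, productivity follows an exponential law

```
C_i = a · exp(d · T_i),          P = (e^d − 1) × 100   [%/°C]
```

where `T_i` is the growing-season mean temperature of cell *i* (about 5–18 °C
across the domain) and `C_i` is growing-season GPP, LAI, or the Beer's-law
fPAR = 1 − e^(−k·LAI). Within each model this spatial sensitivity is nearly
time-invariant, and across an ensemble it predicts the model's **temporal**
feedback factor

```
ΔC(S2−S1) = exp(b · ΔT),         γ = (e^b − 1) × 100   [%/°C]
```

estimated from paired factorial runs (S1: varying CO₂, repeating 1901–1920
climate; S2: varying CO₂ and climate; S2−S1 isolates the climate effect) over
ten overlapping 20-year windows. Regressing γ on P across models and
conditioning on the *observed* spatial sensitivity (a Gaussian constraint)
yields an observationally constrained γ with much smaller uncertainty than the
raw ensemble spread — the space-for-time emergent constraint. Constrained
factors then translate a warming map into predicted percentage change maps,
`((1 + γ/100)^ΔT − 1) × 100`, for comparison with greening observations and
with the CO₂-fertilization term β·ΔCO₂/CO₂.

The package is aimed at carbon-cycle and land-surface model analysts. Because
the archived multi-model runs and satellite products are distributed on
request only, the package ships a fully synthetic TRENDY-like ensemble
generator with known ground truth; every stage of the pipeline is exercised
and validated end-to-end on it.

## Worked example

```python
import math
import borealec as bc

# 8 synthetic models whose true spatial sensitivities span 5-25 %/degC,
# multiplicative noise cv = 0.15, a secular CO2 factor common to S1/S2
config = bc.EnsembleConfig.default(n_models=8, seed=42, noise_cv=0.15,
                                   co2_log_growth=0.002)

# four synthetic observational products scattered about a true 17 %/degC
products = bc.generate_observation_products(true_d=math.log(1.17),
                                            n_products=4, product_noise=2.0,
                                            seed=7)
obs = {"GPP": bc.combine_observed_products(products)}

analysis = bc.run_ensemble_analysis(config=config, obs=obs)
rel = analysis.relation["GPP"]
est = analysis.constrained["GPP"]
print(f"emergent relation: slope {rel.slope:.2f}, R2 {rel.r2:.3f}")
print(f"prior gamma: {analysis.prior['GPP'][0]:.1f} +/- {analysis.prior['GPP'][1]:.1f} %/degC")
print(f"constrained gamma: {est.mean:.1f} +/- {est.sd:.1f} %/degC, Q10 {est.q10:.2f}")
```

prints

```
emergent relation: slope 0.99, R2 1.000
prior gamma: 15.0 +/- 7.0 %/degC
constrained gamma: 16.6 +/- 1.1 %/degC, Q10 1.66
```

The across-model relation is tight (slope ≈ 1: spatial sensitivity predicts
temporal sensitivity), the equal-weight ensemble prior is broad
(15.0 ± 7.0 %/°C), and conditioning on the observed spatial sensitivity
recovers the true γ\* = 17 %/°C within one posterior standard deviation while
shrinking the uncertainty by ~84%. A thin CLI mirrors the workflow:
`borealec simulate`, `borealec run-all`, `borealec co2-effect` (see
`borealec --help`); `run-all` writes `spatial_fits.csv` (columns: model,
scenario, group, variable, a, d, se_d, r2, m, P, sigma_P),
`feedback_factors.csv` and `summary.json`.

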