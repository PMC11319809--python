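"""Synthetic multi-model ensemble of paired factorial (S1/S2) runs.

The generator emulates the statistical structure of a TRENDY-style
terrestrial-model ensemble over high-latitude northern forests, with known
ground truth, so that every downstream estimator (growing season, spatial
exponential fit, S2-S1 feedback factor, emergent constraint) can be tested
without external data.

Construction
------------
Each model is parameterised by an intercept ``a`` and an exponential
temperature coefficient ``d`` per variable.  A cell's growing-season mean
temperature is ``T_gs(i, y) = theta_i + w(y)`` where ``theta_i`` is a
static spatial gradient spanning roughly 5-18 degC from the northern to the
southern edge of the domain and ``w(y)`` is the scenario's warming.  The
noise-free monthly productivity is

    C(i, m, y) = a * exp(d * T_gs(i, y)) * s(i, m) * c(y) * eps

with ``s`` a unimodal seasonal shape whose mean over the cell's growing
season is exactly 1 (so the growing-season mean obeys ``a exp(d T)``
exactly), ``c`` an optional CO2 secular factor common to S1 and S2 (so the
S2-S1 difference isolates climate exactly), and ``eps`` multiplicative
lognormal noise with unit mean.  Monthly temperature is ``T_gs`` plus a
shape-following seasonal excursion whose growing-season mean is zero.

S2 warming is linear in time (``warming_rate`` degC/decade).  S1 tiles the
first 20 years of the S2 climate bit-identically, and S1/S2 share the full
1901-1920 state including the noise realisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import xarray as xr
import yaml

from .containers import MONTHS_PER_YEAR, VARIABLE_UNITS, ScenarioRun

# spatial GS-temperature gradient endpoints (degC) across the latitude span
GS_TEMP_WARM = 18.0
GS_TEMP_COLD = 5.0
# longitudinal temperature anomaly amplitude (degC), a mild "continentality"
LON_TEMP_AMPLITUDE = 0.75
# unimodal monthly productivity template (Jan..Dec, southern-edge timing);
# values are kept well away from 20% of the maximum so growing-season
# membership is stable under climatological noise
SEASON_TEMPLATE = np.array(
    [0.02, 0.02, 0.05, 0.30, 0.70, 1.00, 0.85, 0.55, 0.30, 0.05, 0.02, 0.02]
)
# how many months the seasonal peak advances from the southern to the
# northern edge of the domain
PEAK_POLEWARD_SHIFT = 2
# within-season temperature excursion per unit of (shape - 1), degC
SUMMER_EXCURSION = 5.0
# background PAR level, seasonal amplitude, and longitudinal variation
# (W m-2); the longitudinal term emulates cloudiness gradients orthogonal to
# the temperature field so GS-PAR stays decoupled from GS-T
PAR_MEAN = 110.0
PAR_AMPLITUDE = 8.0
PAR_LON_VARIATION = 4.0

CLIMATE_BLOCK_YEARS = 20  # S1 repeats this many initial years


class ConfigError(ValueError):
    """Raised for ensemble configurations that cannot support the analysis."""


@dataclass(frozen=True)
class ModelParams:
    """Ground-truth coefficients of one synthetic model."""

    model_id: str
    d_gpp: float  # 1/degC
    d_lai: float  # 1/degC
    a_gpp: float = 1.0  # gC m-2 d-1 at 0 degC
    a_lai: float = 0.8  # m2 m-2 at 0 degC

    @property
    def p_gpp(self) -> float:
        """Spatial GPP sensitivity implied by d_gpp, %/degC."""
        return (math.exp(self.d_gpp) - 1.0) * 100.0

    @property
    def p_lai(self) -> float:
        return (math.exp(self.d_lai) - 1.0) * 100.0


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid, cell-center coordinates in degrees."""

    n_lat: int = 7
    n_lon: int = 12
    lat_bounds: tuple[float, float] = (50.0, 78.0)
    lon_bounds: tuple[float, float] = (0.0, 60.0)

    @property
    def dlat(self) -> float:
        return (self.lat_bounds[1] - self.lat_bounds[0]) / self.n_lat

    @property
    def dlon(self) -> float:
        return (self.lon_bounds[1] - self.lon_bounds[0]) / self.n_lon

    @property
    def lat(self) -> np.ndarray:
        return self.lat_bounds[0] + self.dlat * (np.arange(self.n_lat) + 0.5)

    @property
    def lon(self) -> np.ndarray:
        return self.lon_bounds[0] + self.dlon * (np.arange(self.n_lon) + 0.5)


@dataclass
class EnsembleConfig:
    """Full specification of a synthetic ensemble.

    Parameters
    ----------
    models
        Per-model ground-truth coefficients.
    grid
        Native generation grid (coarsened later by the analysis).
    year_start, year_end
        Simulation span; 1901-2010 gives the ten 20-year groups at
        10-year stride used throughout.
    warming_rate
        S2 warming trend, degC per decade.
    noise_cv
        Coefficient of variation of the multiplicative lognormal noise on
        monthly GPP and LAI.
    t_noise_sd
        Additive Gaussian noise on monthly temperature, degC.
    co2_log_growth
        Secular log-growth rate (per year) of the CO2 factor applied
        identically to S1 and S2 productivity; 0 disables it.
    treeline_lat, treeline_width
        Tree-cover taper: full forest cover below
        ``treeline_lat - treeline_width``, tapering to near zero at the
        treeline, emulating models that declare the far north tundra.
    """

    models: Sequence[ModelParams]
    grid: GridSpec = field(default_factory=GridSpec)
    year_start: int = 1901
    year_end: int = 2010
    warming_rate: float = 0.25
    noise_cv: float = 0.15
    t_noise_sd: float = 0.0
    co2_log_growth: float = 0.0
    treeline_lat: float = 76.0
    treeline_width: float = 6.0
    treecover_threshold: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1

    def validate(self) -> None:
        if self.n_models < 2:
            raise ConfigError("need at least 2 models")
        if self.warming_rate < 0:
            raise ConfigError("warming_rate must be >= 0")
        if self.noise_cv < 0 or self.t_noise_sd < 0:
            raise ConfigError("noise levels must be >= 0")
        if self.n_years < CLIMATE_BLOCK_YEARS:
            raise ConfigError("simulation shorter than one climate block")
        for m in self.models:
            if not (np.isfinite(m.d_gpp) and np.isfinite(m.d_lai)):
                raise ConfigError(f"non-finite coefficients for {m.model_id}")
            if m.a_gpp <= 0 or m.a_lai <= 0:
                raise ConfigError(f"non-positive intercepts for {m.model_id}")
        cover = treecover_map(self.grid, self.treeline_lat, self.treeline_width)
        eligible = (cover >= self.treecover_threshold) & (
            self.grid.lat[:, None] > 50.0
        )
        if int(eligible.sum()) < 20:
            raise ConfigError(
                f"only {int(eligible.sum())} forest cells (tree cover >= "
                f"{self.treecover_threshold} north of 50N); need >= 20 - "
                "enlarge the domain or lower the treeline"
            )

    @classmethod
    def default(
        cls,
        n_models: int = 8,
        seed: int = 0,
        noise_cv: float = 0.15,
        p_gpp_range: tuple[float, float] = (5.0, 25.0),
        p_lai_range: tuple[float, float] = (4.0, 20.0),
        **overrides,
    ) -> "EnsembleConfig":
        """Ensemble whose true sensitivities span the given %/degC ranges."""
        p_gpp = np.linspace(*p_gpp_range, n_models)
        p_lai = np.linspace(*p_lai_range, n_models)
        models = [
            ModelParams(
                model_id=chr(ord("A") + i),
                d_gpp=math.log1p(p_gpp[i] / 100.0),
                d_lai=math.log1p(p_lai[i] / 100.0),
            )
            for i in range(n_models)
        ]
        return cls(models=models, seed=seed, noise_cv=noise_cv, **overrides)

    @classmethod
    def from_dict(cls, spec: dict) -> "EnsembleConfig":
        spec = dict(spec)
        if "grid" in spec and isinstance(spec["grid"], dict):
            g = dict(spec["grid"])
            for key in ("lat_bounds", "lon_bounds"):
                if key in g:
                    g[key] = tuple(g[key])
            spec["grid"] = GridSpec(**g)
        if "models" in spec:
            spec["models"] = [
                m if isinstance(m, ModelParams) else ModelParams(**m)
                for m in spec["models"]
            ]
            return cls(**spec)
        n_models = spec.pop("n_models", 8)
        return cls.default(n_models=n_models, **spec)

    @classmethod
    def from_yaml(cls, path) -> "EnsembleConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def treecover_map(
    grid: GridSpec, treeline_lat: float = 76.0, treeline_width: float = 6.0
) -> np.ndarray:
    """Static tree-cover fraction: full cover tapering to ~0 at the treeline."""
    lat = grid.lat[:, None]
    frac = np.clip((treeline_lat - lat) / treeline_width, 0.0, 1.0)
    cover = 0.05 + 0.8 * frac
    return np.broadcast_to(cover, (grid.n_lat, grid.n_lon)).copy()


def seasonal_shape(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Unimodal monthly productivity shape and its growing-season mask.

    Returns ``(s, gs)`` with shapes ``(12, n_lat, n_lon)``.  The peak month
    advances poleward so that growing-season timing (hence GS-PAR) decouples
    from GS temperature.  ``s`` is scaled so its mean over the months where
    the template exceeds 20% of its maximum is exactly 1; those months are
    the generator's ground-truth growing season.
    """
    lat0, lat1 = grid.lat_bounds
    shift = np.rint(
        PEAK_POLEWARD_SHIFT * (grid.lat - lat0) / (lat1 - lat0)
    ).astype(int)  # (n_lat,)
    raw = np.stack(
        [np.roll(SEASON_TEMPLATE, k) for k in shift], axis=1
    )  # (12, n_lat)
    gs = raw > 0.2 * raw.max(axis=0, keepdims=True)
    scale = (raw * gs).sum(axis=0) / gs.sum(axis=0)
    s = raw / scale[None, :]
    s = np.repeat(s[:, :, None], grid.n_lon, axis=2)
    gs = np.repeat(gs[:, :, None], grid.n_lon, axis=2)
    return s, gs


def _theta(grid: GridSpec) -> np.ndarray:
    """Static spatial GS-temperature field (degC), warm south to cold north."""
    lat0, lat1 = grid.lat_bounds
    lon0, lon1 = grid.lon_bounds
    lat_part = GS_TEMP_WARM - (GS_TEMP_WARM - GS_TEMP_COLD) * (
        grid.lat - lat0
    ) / (lat1 - lat0)
    lon_part = LON_TEMP_AMPLITUDE * np.cos(
        2.0 * np.pi * (grid.lon - lon0) / (lon1 - lon0)
    )
    return lat_part[:, None] + lon_part[None, :]


def _lognormal_factors(rng, cv: float, shape) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=shape)


def _model_rng(config: EnsembleConfig, index: int) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(config.n_models)
    return np.random.default_rng(children[index])


def generate_model(
    config: EnsembleConfig, index: int
) -> tuple[ScenarioRun, ScenarioRun]:
    """Generate the (S1, S2) pair for one model. Deterministic given seed."""
    params = config.models[index]
    grid = config.grid
    ny, nm = config.n_years, config.n_years * MONTHS_PER_YEAR
    nlat, nlon = grid.n_lat, grid.n_lon
    rng = _model_rng(config, index)

    theta = _theta(grid)  # (nlat, nlon)
    s, _ = seasonal_shape(grid)  # (12, nlat, nlon)
    cover = treecover_map(grid, config.treeline_lat, config.treeline_width)

    years = np.arange(ny)
    w_s2 = config.warming_rate / 10.0 * years
    w_s1 = w_s2[years % CLIMATE_BLOCK_YEARS]
    co2 = np.exp(config.co2_log_growth * years)

    block = CLIMATE_BLOCK_YEARS * MONTHS_PER_YEAR
    # fixed draw order: shared first block, then S2 remainder, then S1 remainder
    t_shared = (
        rng.normal(0.0, config.t_noise_sd, (block, nlat, nlon))
        if config.t_noise_sd > 0
        else np.zeros((block, nlat, nlon))
    )
    eps_gpp_shared = _lognormal_factors(rng, config.noise_cv, (block, nlat, nlon))
    eps_lai_shared = _lognormal_factors(rng, config.noise_cv, (block, nlat, nlon))
    rest = nm - block
    t_s2_rest = (
        rng.normal(0.0, config.t_noise_sd, (rest, nlat, nlon))
        if config.t_noise_sd > 0
        else np.zeros((rest, nlat, nlon))
    )
    eps_gpp_s2 = np.concatenate(
        [eps_gpp_shared, _lognormal_factors(rng, config.noise_cv, (rest, nlat, nlon))]
    )
    eps_lai_s2 = np.concatenate(
        [eps_lai_shared, _lognormal_factors(rng, config.noise_cv, (rest, nlat, nlon))]
    )
    eps_gpp_s1 = np.concatenate(
        [eps_gpp_shared, _lognormal_factors(rng, config.noise_cv, (rest, nlat, nlon))]
    )
    eps_lai_s1 = np.concatenate(
        [eps_lai_shared, _lognormal_factors(rng, config.noise_cv, (rest, nlat, nlon))]
    )

    def monthly_temperature(w: np.ndarray, t_eps: np.ndarray) -> np.ndarray:
        tgs = theta[None] + w[:, None, None]  # (ny, nlat, nlon)
        tas = tgs[:, None] + SUMMER_EXCURSION * (s - 1.0)[None]
        return tas.reshape(nm, nlat, nlon) + t_eps

    def productivity(a: float, d: float, w: np.ndarray, eps: np.ndarray) -> np.ndarray:
        tgs = theta[None] + w[:, None, None]
        amp = a * np.exp(d * tgs) * co2[:, None, None]  # (ny, nlat, nlon)
        c = amp[:, None] * s[None]
        return c.reshape(nm, nlat, nlon) * eps

    t_eps_s2 = np.concatenate([t_shared, t_s2_rest])
    tas_s2 = monthly_temperature(w_s2, t_eps_s2)
    # S1 climate: tile the first 20-year block bit-identically
    reps = -(-ny // CLIMATE_BLOCK_YEARS)
    tas_s1 = np.tile(tas_s2[:block], (reps, 1, 1))[:nm]

    gpp_s2 = productivity(params.a_gpp, params.d_gpp, w_s2, eps_gpp_s2)
    lai_s2 = productivity(params.a_lai, params.d_lai, w_s2, eps_lai_s2)
    gpp_s1 = productivity(params.a_gpp, params.d_gpp, w_s1, eps_gpp_s1)
    lai_s1 = productivity(params.a_lai, params.d_lai, w_s1, eps_lai_s1)

    month_of_year = np.arange(nm) % MONTHS_PER_YEAR
    lon0, lon1 = grid.lon_bounds
    lon_frac = (grid.lon - lon0) / (lon1 - lon0)
    par_level = PAR_MEAN + PAR_LON_VARIATION * np.sin(4.0 * np.pi * lon_frac)
    par_cycle = PAR_AMPLITUDE * np.cos(
        2.0 * np.pi * (np.arange(MONTHS_PER_YEAR) - 6.0) / MONTHS_PER_YEAR
    )
    par_clim = par_level[None, None, :] + par_cycle[:, None, None] * np.ones(
        (1, nlat, 1)
    )
    par = np.take(par_clim, month_of_year, axis=0)

    def dataset(scenario, tas, gpp, lai) -> ScenarioRun:
        ds = xr.Dataset(
            {
                "gpp": (("time", "lat", "lon"), gpp, {"units": VARIABLE_UNITS["gpp"]}),
                "lai": (("time", "lat", "lon"), lai, {"units": VARIABLE_UNITS["lai"]}),
                "tas": (("time", "lat", "lon"), tas, {"units": VARIABLE_UNITS["tas"]}),
                "par": (("time", "lat", "lon"), par, {"units": VARIABLE_UNITS["par"]}),
                "treecover": (("lat", "lon"), cover, {"units": VARIABLE_UNITS["treecover"]}),
            },
            coords={
                "time": np.arange(nm),
                "lat": grid.lat,
                "lon": grid.lon,
            },
            attrs={
                "scenario": scenario,
                "model_id": params.model_id,
                "seed": config.seed,
                "start_year": config.year_start,
            },
        )
        return ScenarioRun(
            model_id=params.model_id,
            scenario=scenario,
            data=ds,
            start_year=config.year_start,
        )

    return dataset("S1", tas_s1, gpp_s1, lai_s1), dataset("S2", tas_s2, gpp_s2, lai_s2)


def iter_ensemble(config: EnsembleConfig) -> Iterator[tuple[ScenarioRun, ScenarioRun]]:
    """Yield (S1, S2) pairs one model at a time (memory-friendly)."""
    for index in range(config.n_models):
        yield generate_model(config, index)


def generate_ensemble(config: EnsembleConfig) -> list[tuple[ScenarioRun, ScenarioRun]]:
    return list(iter_ensemble(config))


def generate_observation_products(
    true_d: float,
    n_products: int = 4,
    product_noise: float = 2.0,
    seed: int = 0,
    sigma_fit: float | None = None,
) -> list[tuple[float, float]]:
    """Synthetic observational spatial-sensitivity products.

    Stand-ins for independent satellite/upscaling products: per-product
    sensitivities scatter around the true ``(e^d - 1) * 100`` %/degC with
    Gaussian spread ``product_noise``; each carries a per-product fitting
    uncertainty ``sigma_fit`` (defaults to ``product_noise``).
    """
    if n_products < 1:
        raise ValueError("n_products must be >= 1")
    p_true = (math.exp(true_d) - 1.0) * 100.0
    rng = np.random.default_rng(seed)
    if product_noise > 0:
        p = p_true + rng.normal(0.0, product_noise, n_products)
    else:
        p = np.full(n_products, p_true)
    sig = product_noise if sigma_fit is None else sigma_fit
    return [(float(pi), float(sig)) for pi in p]
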