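"""Synthetic panel generator with known ground truth.

Emulates the statistical structure the analysis assumes, so every
downstream stage can be validated against generating parameters:

* **Exposure fields** are additive: ``X_itp = m_p + S_ip + T_tp + eps_itp``
  with unit effects ``S_i`` drawn once per unit from a cross-pollutant
  correlated normal (the spatial component), an area-wide daily signal
  ``T_t`` = seasonal sinusoid + AR(1) with cross-pollutant correlated
  innovations (the temporal component), and independent unit-day noise.
  The construction reproduces exactly the spatial/temporal variance
  partition the analysis exploits at O(n) cost.  Negative concentrations
  are clipped to 0 and the clip rate is logged.
* **Meteorology** (shared across units): annual sinusoid + AR(1) noise;
  humidity clipped to [0, 100].
* **Counts** are drawn from the zero-inflated negative binomial mixed model
  itself: one random intercept per unit, structural zeros independent
  across unit-days, and confounder effects expressed in the same
  natural-spline bases the design builder uses — so generating coefficients
  live in the fitted parameterization and recovery tests are exact.

Default preset configurations: ``lambeth_like`` (177 units, 2009-2013,
1304 weekdays per unit, exposure moments/correlations set to the study
area's printed summaries) and ``desk`` (50 units x 1 year) for fast
simulation studies.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as design_mod
from .errors import ConfigError, SimulationError
from .panel_io import POLLUTANTS, PanelDataset, count_column, validate_panel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PollutantField:
    """Marginal structure of one pollutant's synthetic field (ug/m3)."""

    mean: float
    spatial_sd: float  # SD of unit long-term means
    temporal_sd: float  # SD of the area-wide daily signal (seasonal + AR1)
    unit_noise_sd: float  # independent unit-day noise
    seasonal_amplitude: float = 0.0
    peak_doy: float = 15.0  # day of year where the seasonal term peaks
    ar1: float = 0.7

    def __post_init__(self) -> None:
        for name in ("spatial_sd", "temporal_sd", "unit_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not -1 < self.ar1 < 1:
            raise ConfigError("ar1 coefficient must be in (-1, 1)")
        if self.seasonal_amplitude**2 / 2 > self.temporal_sd**2 + 1e-12:
            raise ConfigError(
                "seasonal amplitude implies more variance than temporal_sd allows"
            )


def _check_corr(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, float)
    if mat.shape != (len(POLLUTANTS), len(POLLUTANTS)):
        raise ConfigError(f"{name} must be {len(POLLUTANTS)}x{len(POLLUTANTS)}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ConfigError(f"{name} must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
        raise ConfigError(f"{name} must have a unit diagonal")
    if np.linalg.eigvalsh(mat).min() < -1e-8:
        raise ConfigError(f"{name} is not positive semi-definite")
    return mat


@dataclass
class ExposureFieldConfig:
    """Per-pollutant marginals plus cross-pollutant correlation structure.

    Correlation matrices are ordered like :data:`airpanel.panel_io.POLLUTANTS`
    (no2, pm10, pm25, o3); the temporal matrix correlates the AR(1)
    innovations of the daily signals, the spatial matrix the unit effects.
    """

    pollutants: dict[str, PollutantField]
    temporal_corr: np.ndarray
    spatial_corr: np.ndarray

    def __post_init__(self) -> None:
        missing = set(POLLUTANTS) - set(self.pollutants)
        if missing:
            raise ConfigError(f"exposure config missing pollutant(s): {sorted(missing)}")
        self.temporal_corr = _check_corr(self.temporal_corr, "temporal_corr")
        self.spatial_corr = _check_corr(self.spatial_corr, "spatial_corr")


@dataclass
class SeasonalSeries:
    """Annual sinusoid + AR(1) noise around a mean."""

    mean: float
    sd: float
    seasonal_amplitude: float = 0.0
    peak_doy: float = 196.0
    ar1: float = 0.7

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError("sd must be >= 0")
        if not -1 < self.ar1 < 1:
            raise ConfigError("ar1 must be in (-1, 1)")
        if self.seasonal_amplitude**2 / 2 > self.sd**2 + 1e-12:
            raise ConfigError("seasonal amplitude exceeds total sd budget")


@dataclass
class MeteorologyConfig:
    temperature: SeasonalSeries
    humidity: SeasonalSeries


@dataclass
class TrueModelParams:
    """Generating coefficients for one outcome group x age band.

    ``beta_short``/``beta_long`` are per ug/m3 of the named pollutant's
    daily deviation and study-period unit mean; spline coefficients are in
    the design builder's natural-spline bases; ``weekday`` maps dummy names
    (Tue..Fri) to log-rate offsets against Monday.
    """

    pollutant: str
    intercept: float
    beta_short: float = 0.0
    beta_long: float = 0.0
    temperature: tuple[float, ...] = (0.0, 0.0, 0.0)
    humidity: tuple[float, ...] = (0.0, 0.0, 0.0)
    trend: tuple[float, ...] = ()
    weekday: dict[str, float] = field(default_factory=dict)
    pct_elderly: float = 0.0
    deprivation: float = 0.0
    gamma0: float = -30.0  # logit of structural-zero probability
    theta: float = 1.0
    sigma_b: float = 0.0

    def __post_init__(self) -> None:
        if self.pollutant not in POLLUTANTS:
            raise ConfigError(f"unknown pollutant {self.pollutant!r}")
        if self.theta <= 0:
            raise ConfigError("theta must be > 0")
        if self.sigma_b < 0:
            raise ConfigError("sigma_b must be >= 0")
        self.temperature = tuple(self.temperature)
        self.humidity = tuple(self.humidity)
        self.trend = tuple(self.trend)

    @property
    def pi(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.gamma0)))


@dataclass
class UnitCovariateConfig:
    pct_elderly_mean: float = 9.0
    pct_elderly_sd: float = 3.0
    deprivation_mean: float = 25.0
    deprivation_sd: float = 8.0


@dataclass
class StudyConfig:
    """Full recipe for one synthetic study."""

    n_units: int
    start: date
    end: date
    exposure: ExposureFieldConfig
    meteorology: MeteorologyConfig
    outcomes: dict[tuple[str, str], TrueModelParams]  # (group, age_band) -> params
    unit_covariates: UnitCovariateConfig = field(default_factory=UnitCovariateConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ConfigError("need n_units >= 2")
        if (pd.Timestamp(self.end) - pd.Timestamp(self.start)).days < 55:
            raise ConfigError("study span must cover at least 8 weeks")
        if not self.outcomes:
            raise ConfigError("at least one (outcome_group, age_band) is required")

    @property
    def outcome_groups(self) -> tuple[str, ...]:
        seen: list[str] = []
        for g, _ in self.outcomes:
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    @property
    def age_bands(self) -> tuple[str, ...]:
        seen: list[str] = []
        for _, a in self.outcomes:
            if a not in seen:
                seen.append(a)
        return tuple(seen)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        try:
            pollutants = {
                p: PollutantField(**v) for p, v in raw["exposure"]["pollutants"].items()
            }
            exposure = ExposureFieldConfig(
                pollutants=pollutants,
                temporal_corr=np.asarray(raw["exposure"]["temporal_corr"], float),
                spatial_corr=np.asarray(raw["exposure"]["spatial_corr"], float),
            )
            met = MeteorologyConfig(
                temperature=SeasonalSeries(**raw["meteorology"]["temperature"]),
                humidity=SeasonalSeries(**raw["meteorology"]["humidity"]),
            )
            outcomes = {}
            for g, bands in raw["outcomes"].items():
                for a, pr in bands.items():
                    pr = dict(pr)
                    for k in ("temperature", "humidity", "trend"):
                        if k in pr:
                            pr[k] = tuple(pr[k])
                    outcomes[(g, a)] = TrueModelParams(**pr)
            uc = UnitCovariateConfig(**raw.get("unit_covariates", {}))
            return cls(
                n_units=int(raw["n_units"]),
                start=pd.Timestamp(raw["start"]).date(),
                end=pd.Timestamp(raw["end"]).date(),
                exposure=exposure,
                meteorology=met,
                outcomes=outcomes,
                unit_covariates=uc,
                seed=int(raw.get("seed", 0)),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"invalid study config: {exc}") from exc


def load_preset(name: str) -> StudyConfig:
    """Load a shipped preset config: ``desk`` or ``lambeth_like``."""
    ref = resources.files("airpanel").joinpath(f"presets/{name}.yaml")
    if not ref.is_file():
        raise ConfigError(f"no preset named {name!r}")
    return StudyConfig.from_dict(yaml.safe_load(ref.read_text()))


# ---------------------------------------------------------------------------
# generators


def _seasonal(dates: pd.DatetimeIndex, amplitude: float, peak_doy: float) -> np.ndarray:
    doy = dates.dayofyear.to_numpy(float)
    return amplitude * np.cos(2 * np.pi * (doy - peak_doy) / 365.25)


def _ar1(n: int, rho: float, stationary_sd: float, innov: np.ndarray) -> np.ndarray:
    """AR(1) with given stationary SD driven by standard-normal innovations."""
    if stationary_sd == 0:
        return np.zeros(n)
    u = np.empty(n)
    u[0] = stationary_sd * innov[0]
    scale = stationary_sd * np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        u[t] = rho * u[t - 1] + scale * innov[t]
    return u


def generate_exposure_fields(
    cfg: ExposureFieldConfig,
    n_units: int,
    dates: pd.DatetimeIndex,
    rng: np.random.Generator | int,
) -> tuple[dict[str, np.ndarray], dict]:
    """Draw the four pollutant fields as (n_units, n_days) arrays.

    Returns the fields plus an info dict with the fraction of unit-days
    clipped at zero per pollutant.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_days = len(dates)
    P = len(POLLUTANTS)

    def chol(mat):
        w, V = np.linalg.eigh(mat)
        w = np.maximum(w, 0.0)
        return V * np.sqrt(w)

    Ls, Lt = chol(cfg.spatial_corr), chol(cfg.temporal_corr)
    spatial_sd = np.array([cfg.pollutants[p].spatial_sd for p in POLLUTANTS])
    S = (rng.standard_normal((n_units, P)) @ Ls.T) * spatial_sd  # unit effects

    innov = rng.standard_normal((n_days, P)) @ Lt.T  # correlated AR innovations
    T = np.empty((n_days, P))
    for j, p in enumerate(POLLUTANTS):
        pf = cfg.pollutants[p]
        sd_u = np.sqrt(max(pf.temporal_sd**2 - pf.seasonal_amplitude**2 / 2.0, 0.0))
        T[:, j] = _seasonal(dates, pf.seasonal_amplitude, pf.peak_doy) + _ar1(
            n_days, pf.ar1, sd_u, innov[:, j]
        )

    fields, clip_rates = {}, {}
    for j, p in enumerate(POLLUTANTS):
        pf = cfg.pollutants[p]
        eps = pf.unit_noise_sd * rng.standard_normal((n_units, n_days))
        X = pf.mean + S[:, j : j + 1] + T[None, :, j] + eps
        clipped = X < 0
        clip_rates[p] = float(clipped.mean())
        if clip_rates[p] > 0:
            logger.info("clipped %.3f%% of %s unit-days at 0", 100 * clip_rates[p], p)
        fields[p] = np.where(clipped, 0.0, X)
    return fields, {"clip_rate": clip_rates}


def generate_meteorology(
    cfg: MeteorologyConfig, dates: pd.DatetimeIndex, rng: np.random.Generator | int
) -> tuple[np.ndarray, np.ndarray]:
    """Daily temperature (C) and relative humidity (%), shared across units."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = len(dates)
    out = []
    for s in (cfg.temperature, cfg.humidity):
        sd_u = np.sqrt(max(s.sd**2 - s.seasonal_amplitude**2 / 2.0, 0.0))
        series = (
            s.mean
            + _seasonal(dates, s.seasonal_amplitude, s.peak_doy)
            + _ar1(n, s.ar1, sd_u, rng.standard_normal(n))
        )
        out.append(series)
    temp, hum = out
    return temp, np.clip(hum, 0.0, 100.0)


def _params_to_beta(params: TrueModelParams, columns: pd.Index, trend_df: int) -> np.ndarray:
    if len(params.trend) not in (0, trend_df):
        raise ConfigError(
            f"trend coefficients have length {len(params.trend)}, "
            f"design trend spline has {trend_df} df"
        )
    trend = params.trend or (0.0,) * trend_df
    values = {
        "const": params.intercept,
        f"{params.pollutant}_short": params.beta_short,
        f"{params.pollutant}_long": params.beta_long,
        "pct_elderly": params.pct_elderly,
        "deprivation": params.deprivation,
    }
    for j, v in enumerate(params.temperature):
        values[f"temp_ns_{j + 1}"] = v
    for j, v in enumerate(params.humidity):
        values[f"hum_ns_{j + 1}"] = v
    for j, v in enumerate(trend):
        values[f"trend_ns_{j + 1}"] = v
    for name, v in params.weekday.items():
        values[f"dow_{name}"] = v
    beta = np.zeros(len(columns))
    for j, c in enumerate(columns):
        if c in values:
            beta[j] = values.pop(c)
    # weekday names absent from a weekday-only panel (Sat/Sun) are fine
    leftovers = set(values) - {f"dow_{d}" for d in ("Sat", "Sun")}
    if leftovers:
        raise ConfigError(
            f"true parameters name terms absent from the design: {sorted(leftovers)}"
        )
    return beta


def generate_counts(
    panel: PanelDataset,
    params: TrueModelParams,
    outcome_group: str,
    age_band: str,
    rng: np.random.Generator | int,
) -> pd.Series:
    """Draw one weekday count series from the ZINB mixed model.

    Builds the lag-0 design on the panel's exposures/meteorology (so the
    generating coefficients are expressed in the fitted parameterization),
    draws one ``b_i ~ N(0, sigma_b^2)`` per unit, forms
    ``mu_it = exp(x_it' beta + b_i)``, replaces each observation by a
    structural zero with probability ``pi = logistic(gamma0)`` and
    otherwise draws NB(mu, theta).  Returns counts indexed by
    (unit_id, date).
    """
    from .exposure import LagSpec, decompose

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    # design construction needs a populated count column; use a zero
    # placeholder on weekdays (y is not read when forming X)
    work = dataclasses.replace(panel, daily=panel.daily.copy())
    ycol = count_column(outcome_group, age_band)
    wd = pd.to_datetime(work.daily["date"]).dt.dayofweek < 5
    work.daily.loc[wd, ycol] = 0.0
    dm = design_mod.build_design(
        work,
        decompose(work, params.pollutant),
        LagSpec("lag0"),
        outcome_group,
        age_band,
        rank_check=False,
    )
    trend_df = design_mod.trend_df_for(panel.study_start, panel.study_end)
    beta = _params_to_beta(params, dm.X.columns, trend_df)
    b = params.sigma_b * rng.standard_normal(dm.n_units)
    eta = dm.X.to_numpy(float) @ beta + b[dm.groups]
    if np.max(eta) > 30:
        raise SimulationError(
            f"linear predictor reaches {np.max(eta):.1f} > 30; "
            "rescale the generating parameters"
        )
    mu = np.exp(eta)
    if params.theta > 1e6:  # Poisson limit, NB sampler unstable there
        y = rng.poisson(mu)
    else:
        y = rng.negative_binomial(params.theta, params.theta / (params.theta + mu))
    pi = params.pi
    if pi > 0:
        y = np.where(rng.random(len(y)) < pi, 0, y)
    idx = pd.MultiIndex.from_frame(dm.row_index[["unit_id", "date"]])
    return pd.Series(y, index=idx, name=count_column(outcome_group, age_band))


def generate_study(cfg: StudyConfig) -> PanelDataset:
    """Compose exposures, meteorology and counts into a validated panel.

    Deterministic given (config, seed); the generating parameters are
    attached as ``dataset.true_params`` keyed by (outcome_group, age_band).
    """
    root = np.random.SeedSequence(cfg.seed)
    s_units, s_exp, s_met, s_counts = root.spawn(4)
    dates = pd.date_range(cfg.start, cfg.end, freq="D")

    rng_u = np.random.default_rng(s_units)
    uc = cfg.unit_covariates
    width = max(4, len(str(cfg.n_units)))
    units = pd.DataFrame(
        {
            "unit_id": [f"u{j:0{width}d}" for j in range(1, cfg.n_units + 1)],
            "pct_elderly": np.clip(
                uc.pct_elderly_mean + uc.pct_elderly_sd * rng_u.standard_normal(cfg.n_units),
                0.0,
                100.0,
            ),
            "deprivation": uc.deprivation_mean
            + uc.deprivation_sd * rng_u.standard_normal(cfg.n_units),
        }
    )

    fields, _info = generate_exposure_fields(
        cfg.exposure, cfg.n_units, dates, np.random.default_rng(s_exp)
    )
    temp, hum = generate_meteorology(cfg.meteorology, dates, np.random.default_rng(s_met))

    n_days = len(dates)
    daily = pd.DataFrame(
        {
            "unit_id": np.repeat(units["unit_id"].to_numpy(), n_days),
            "date": np.tile(dates.to_numpy(), cfg.n_units),
        }
    )
    for p in POLLUTANTS:
        daily[p] = fields[p].reshape(-1)
    daily["temperature"] = np.tile(temp, cfg.n_units)
    daily["humidity"] = np.tile(hum, cfg.n_units)

    groups = cfg.outcome_groups
    bands = cfg.age_bands
    for g in groups:
        for a in bands:
            if (g, a) not in cfg.outcomes:
                raise ConfigError(f"no generating parameters for ({g!r}, {a!r})")
            daily[count_column(g, a)] = np.nan

    panel = PanelDataset(
        units=units,
        daily=daily,
        study_start=pd.Timestamp(cfg.start).date(),
        study_end=pd.Timestamp(cfg.end).date(),
        age_bands=bands,
        outcome_groups=groups,
    )

    rng_c = np.random.default_rng(s_counts)
    key = pd.MultiIndex.from_frame(daily[["unit_id", "date"]])
    for (g, a), params in cfg.outcomes.items():
        counts = generate_counts(panel, params, g, a, rng_c)
        aligned = counts.reindex(key)
        panel.daily[count_column(g, a)] = aligned.to_numpy()

    validate_panel(panel)
    panel.true_params = {k: dataclasses.replace(v) for k, v in cfg.outcomes.items()}
    return panel
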