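"""Effect estimation grid and IQR-scaled reporting.

Fitted log-rate coefficients are reported as the percent change in expected
counts for an interquartile-range increase in exposure::

    pct = 100 * (exp(beta * IQR) - 1)

with 95% Wald confidence limits ``100 * (exp((beta +/- 1.96 se) * IQR) - 1)``.
Short-term (daily deviation) terms are scaled by the temporal IQR of the
daily area-average series; long-term (unit mean) terms by the spatial IQR
of the per-unit study-period means.

:func:`run_analysis` orchestrates the analysis grid -- pollutant x lag x
outcome x age band, optionally adjusted for a co-pollutant (same-lag
short-term term plus long-term mean) -- fitting the mixed ZINB model per
cell; individual cell failures are recorded, not fatal.
:func:`fit_poisson_timeseries` is the conventional single-area sensitivity
check: counts summed over units per weekday, exposures area-averaged, and a
Poisson log-linear model with the same temporal confounders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    DesignMatrices,
    SplineSpec,
    build_design,
    natural_spline_basis,
    trend_df_for,
    weekday_dummies,
)
from .errors import AirPanelError, DesignError, FitError
from .exposure import LagSpec, apply_lag, area_average, compute_iqrs, decompose
from .panel_io import POLLUTANTS, PanelDataset, count_column
from .zinb import ZINBMixedFit, ZINBMixedSpec, fit_zinb_mixed

logger = logging.getLogger(__name__)

Z_95 = 1.96  # normal multiplier for the 95% Wald interval


@dataclass
class EffectEstimate:
    """% change per IQR with 95% CI for one grid cell."""

    pollutant: str
    term: str  # "short" or "long"
    lag: str  # lag label ("lag0".."week_avg"); long-term effects carry the
    # lag of the model they were estimated in
    outcome_group: str
    age_band: str
    pct_change: float
    ci_low: float
    ci_high: float
    iqr_used: float
    coef: float
    se: float
    adjusted_for: str | None = None
    model: str = "zinb_mixed"

    def as_dict(self) -> dict:
        return {
            "pollutant": self.pollutant,
            "term": self.term,
            "lag": self.lag,
            "outcome_group": self.outcome_group,
            "age_band": self.age_band,
            "pct_change": self.pct_change,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "iqr_used": self.iqr_used,
            "coef": self.coef,
            "se": self.se,
            "adjusted_for": self.adjusted_for or "",
            "model": self.model,
        }


def percent_change_per_iqr(
    coef: float,
    se: float,
    iqr: float,
    *,
    pollutant: str = "",
    term: str = "short",
    lag: str = "lag0",
    outcome_group: str = "",
    age_band: str = "",
    adjusted_for: str | None = None,
    model: str = "zinb_mixed",
) -> EffectEstimate:
    """Transform a log-rate coefficient into % change per IQR with 95% CI."""
    if iqr < 0:
        raise AirPanelError("iqr must be >= 0")
    if se < 0:
        raise AirPanelError("se must be >= 0")
    pct = 100.0 * np.expm1(coef * iqr)
    lo = 100.0 * np.expm1((coef - Z_95 * se) * iqr)
    hi = 100.0 * np.expm1((coef + Z_95 * se) * iqr)
    return EffectEstimate(
        pollutant=pollutant,
        term=term,
        lag=lag,
        outcome_group=outcome_group,
        age_band=age_band,
        pct_change=float(pct),
        ci_low=float(lo),
        ci_high=float(hi),
        iqr_used=float(iqr),
        coef=float(coef),
        se=float(se),
        adjusted_for=adjusted_for,
        model=model,
    )


@dataclass
class CellFailure:
    """Record of one analysis-grid cell that could not be estimated."""

    pollutant: str
    lag: str
    outcome_group: str
    age_band: str
    error: str


@dataclass
class AnalysisResult:
    estimates: list[EffectEstimate] = field(default_factory=list)
    failures: list[CellFailure] = field(default_factory=list)
    fits: dict[str, ZINBMixedFit] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.as_dict() for e in self.estimates])


def _estimates_from_fit(
    fit: ZINBMixedFit,
    pollutant: str,
    lag: LagSpec,
    outcome_group: str,
    age_band: str,
    iqrs,
    adjusted_for: str | None,
) -> list[EffectEstimate]:
    out = []
    for term, iqr_val in (("short", iqrs.temporal_iqr), ("long", iqrs.spatial_iqr)):
        label = f"{pollutant}_{term}"
        out.append(
            percent_change_per_iqr(
                float(fit.beta[label]),
                fit.se(label),
                iqr_val,
                pollutant=pollutant,
                term=term,
                lag=lag.label,
                outcome_group=outcome_group,
                age_band=age_band,
                adjusted_for=adjusted_for,
            )
        )
    return out


def run_analysis(
    panel: PanelDataset,
    pollutant: str,
    outcome_group: str,
    age_band: str,
    lags: list[LagSpec] | None = None,
    co_pollutant: str | None = None,
    n_nodes: int = 15,
    include_co_long_term: bool = True,
    **fit_kwargs,
) -> AnalysisResult:
    """Fit the mixed ZINB model for each lag and report IQR-scaled effects.

    Per lag the pipeline is decompose -> build_design -> fit_zinb_mixed ->
    one short-term and one long-term estimate.  Two-pollutant adjustment
    adds the co-pollutant's short-term term at the same lag plus (by
    default) its long-term mean.  Failing cells are collected in
    ``result.failures``.
    """
    if lags is not None and len(lags) == 0:
        raise AirPanelError("empty lag list")
    lags = lags or [LagSpec("lag0")]
    dec = decompose(panel, pollutant)
    co_dec = decompose(panel, co_pollutant) if co_pollutant else None
    iqrs = compute_iqrs(panel, pollutant)

    result = AnalysisResult()
    for lag in lags:
        try:
            dm = build_design(
                panel, dec, lag, outcome_group, age_band, co_pollutant=co_dec
            )
            if co_dec is not None and not include_co_long_term:
                dm.X = dm.X.drop(columns=[f"{co_dec.pollutant}_long"])
            spec = ZINBMixedSpec(design=dm, n_nodes=n_nodes, **fit_kwargs)
            fit = fit_zinb_mixed(spec)
            logger.info(
                "fit %s %s %s/%s: loglik=%.2f converged=%s",
                pollutant, lag.label, outcome_group, age_band, fit.loglik, fit.converged,
            )
            result.fits[lag.label] = fit
            result.estimates.extend(
                _estimates_from_fit(
                    fit, pollutant, lag, outcome_group, age_band, iqrs, co_pollutant
                )
            )
        except (FitError, DesignError) as exc:
            logger.warning("cell (%s, %s) failed: %s", pollutant, lag.label, exc)
            result.failures.append(
                CellFailure(pollutant, lag.label, outcome_group, age_band, str(exc))
            )
    return result


def run_grid(
    panel: PanelDataset,
    pollutants: list[str] | None = None,
    lags: list[LagSpec] | None = None,
    outcome_group: str | None = None,
    age_band: str | None = None,
    **kwargs,
) -> AnalysisResult:
    """Convenience loop of :func:`run_analysis` over several pollutants."""
    pollutants = pollutants or list(POLLUTANTS)
    outcome_group = outcome_group or panel.outcome_groups[0]
    age_band = age_band or panel.age_bands[0]
    merged = AnalysisResult()
    for p in pollutants:
        r = run_analysis(panel, p, outcome_group, age_band, lags=lags, **kwargs)
        merged.estimates.extend(r.estimates)
        merged.failures.extend(r.failures)
        for k, v in r.fits.items():
            merged.fits[f"{p}:{k}"] = v
    return merged


# ---------------------------------------------------------------------------
# Poisson time-series sensitivity model


@dataclass
class PoissonTSFit:
    estimate: EffectEstimate
    coef: pd.Series
    se_unscaled: float
    overdispersion: float  # Pearson chi2 / df
    loglik: float
    n_obs: int


def aggregate_daily(panel: PanelDataset, pollutant: str, outcome_group: str,
                    age_band: str) -> pd.DataFrame:
    """Area-aggregated weekday series: summed counts, averaged exposure."""
    ycol = count_column(outcome_group, age_band)
    daily = panel.daily.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    counts = (
        daily.loc[daily["date"].dt.dayofweek < 5]
        .groupby("date")[ycol]
        .sum()
        .sort_index()
    )
    out = pd.DataFrame({"y": counts})
    for col in (pollutant, "temperature", "humidity"):
        out[col] = area_average(panel, col).reindex(out.index)
    return out


def fit_poisson_timeseries(
    panel: PanelDataset,
    pollutant: str,
    lag: LagSpec | None = None,
    outcome_group: str | None = None,
    age_band: str | None = None,
    scale_ses: bool = False,
) -> PoissonTSFit:
    """Single-area Poisson time-series model (short-term effect only).

    Counts are summed over units per weekday, exposures averaged over units
    per day; the model adjusts for weekday dummies and natural splines of
    temperature, humidity and trend (same df rules as the panel model), fit
    by IRLS.  The short-term effect is scaled by the temporal IQR.  With
    ``scale_ses=True`` the Pearson overdispersion factor inflates the SE
    (quasi-Poisson).
    """
    import statsmodels.api as sm

    lag = lag or LagSpec("lag0")
    outcome_group = outcome_group or panel.outcome_groups[0]
    age_band = age_band or panel.age_bands[0]
    if (pd.Timestamp(panel.study_end) - pd.Timestamp(panel.study_start)).days < 55:
        raise AirPanelError("Poisson time-series model needs >= 8 weeks of data")

    agg = aggregate_daily(panel, pollutant, outcome_group, age_band)
    # deviation of the area-average series from its mean, then lagged
    expo_all_days = area_average(panel, pollutant)
    dev = expo_all_days - expo_all_days.mean()
    lagged = apply_lag(dev, lag)
    agg["short"] = lagged.reindex(agg.index)
    agg = agg.dropna(subset=["short"])

    all_days = pd.date_range(panel.study_start, panel.study_end, freq="D")
    day_index = pd.Series(np.arange(len(all_days)), index=all_days)
    X = pd.DataFrame({"const": np.ones(len(agg))})
    X[f"{pollutant}_short"] = agg["short"].to_numpy()
    X = pd.concat(
        [
            X,
            natural_spline_basis(agg["temperature"].to_numpy(), SplineSpec("temp", 3)),
            natural_spline_basis(agg["humidity"].to_numpy(), SplineSpec("hum", 3)),
            natural_spline_basis(
                day_index.reindex(agg.index).to_numpy(),
                SplineSpec("trend", trend_df_for(panel.study_start, panel.study_end)),
            ),
            weekday_dummies(pd.DatetimeIndex(agg.index)),
        ],
        axis=1,
    )

    model = sm.GLM(agg["y"].to_numpy(), X.to_numpy(float), family=sm.families.Poisson())
    try:
        res = model.fit(maxiter=100, tol=1e-10)
    except Exception as exc:  # pragma: no cover - IRLS rarely throws here
        raise FitError(f"Poisson IRLS failed: {exc}") from exc
    if not res.converged:
        raise FitError("Poisson IRLS did not converge in 100 iterations")

    coef = pd.Series(res.params, index=X.columns)
    j = list(X.columns).index(f"{pollutant}_short")
    se = float(np.sqrt(res.cov_params()[j, j]))
    mu = res.mu
    pearson = float(np.sum((agg["y"].to_numpy() - mu) ** 2 / mu) / (len(agg) - X.shape[1]))
    se_used = se * np.sqrt(pearson) if scale_ses else se

    iqrs = compute_iqrs(panel, pollutant)
    est = percent_change_per_iqr(
        float(coef[f"{pollutant}_short"]),
        se_used,
        iqrs.temporal_iqr,
        pollutant=pollutant,
        term="short",
        lag=lag.label,
        outcome_group=outcome_group,
        age_band=age_band,
        model="poisson_ts",
    )
    return PoissonTSFit(
        estimate=est,
        coef=coef,
        se_unscaled=se,
        overdispersion=pearson,
        loglik=float(res.llf),
        n_obs=len(agg),
    )


# ---------------------------------------------------------------------------
# reporting


def render_report(
    estimates: list[EffectEstimate],
    iqrs: pd.DataFrame | None,
    out_dir: str | Path,
    fits: dict | None = None,
) -> list[Path]:
    """Write the estimate grid as CSV plus one forest-style lag plot per
    pollutant; deterministic given identical inputs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not estimates:
        raise AirPanelError("no estimates to render")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    frame = pd.DataFrame([e.as_dict() for e in estimates])
    grid_path = out_dir / "estimates.csv"
    frame.to_csv(grid_path, index=False, float_format="%.10g")
    written.append(grid_path)

    if iqrs is not None:
        iqr_path = out_dir / "iqrs.csv"
        iqrs.to_csv(iqr_path, index=False, float_format="%.10g")
        written.append(iqr_path)

    lag_order = ["lag0", "lag1", "lag2", "week_avg"]
    for pollutant in sorted(frame["pollutant"].unique()):
        sub = frame[(frame["pollutant"] == pollutant) & (frame["term"] == "short")]
        if sub.empty:
            continue
        sub = sub.set_index("lag").reindex([l for l in lag_order if l in set(sub["lag"])])
        fig, ax = plt.subplots(figsize=(5, 3.2))
        xs = np.arange(len(sub))
        pct = sub["pct_change"].to_numpy(float)
        ax.errorbar(
            xs,
            pct,
            yerr=[pct - sub["ci_low"].to_numpy(float), sub["ci_high"].to_numpy(float) - pct],
            fmt="o",
            capsize=3,
        )
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xticks(xs, sub.index)
        ax.set_ylabel("% change per IQR")
        ax.set_title(f"{pollutant}: short-term effect by lag")
        fig.tight_layout()
        png = out_dir / f"forest_{pollutant}.png"
        fig.savefig(png, dpi=120, metadata={"Software": "airpanel"})
        plt.close(fig)
        written.append(png)

    if fits:
        lines = []
        for k, f in fits.items():
            lines.append(f"== {k} ==")
            lines.append(f.summary())
            lines.append("")
        lines.append("Note: nominal 95% CIs; no multiple-testing adjustment.")
        fit_path = out_dir / "fits.txt"
        fit_path.write_text("\n".join(lines))
        written.append(fit_path)
    return written
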