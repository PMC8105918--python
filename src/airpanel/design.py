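"""Fixed-effect design matrices for the count model.

The count part of the model adjusts for:

* the pollutant's short-term term (lagged daily deviation) and long-term
  term (unit study-period mean),
* temperature and relative humidity as natural cubic splines (3 df each),
* a long-term time trend as a natural spline over the sequential day index
  with 6 df per study year,
* day-of-week dummies (Monday reference; the column set follows the days
  actually observed, so a weekday-only panel yields 4 dummies and a full
  week yields 6),
* two unit-level covariates: percentage of residents aged >= 65 and a
  deprivation score,
* optionally a co-pollutant's short-term (same lag) and long-term terms for
  two-pollutant adjustment.

The zero-inflation part is intercept-only by default; a flag mirrors the
count-part covariates for sensitivity analyses.

Natural splines use the classical construction: a cubic B-spline basis with
interior knots at equally spaced quantiles and boundary knots at the data
extremes, projected onto the null space of the boundary second-derivative
constraints, so each basis column is linear beyond the boundary knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import qr as _pivoted_qr

from .errors import DesignError
from .exposure import DecomposedExposure, LagSpec, apply_lag
from .panel_io import PanelDataset, count_column

WEEKDAY_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


@dataclass(frozen=True)
class SplineSpec:
    """Natural-spline configuration for one continuous confounder.

    ``df`` basis columns; interior knots at equally spaced quantiles of the
    observed values, boundary knots at min/max.
    """

    variable: str
    df: int

    def __post_init__(self) -> None:
        if self.df < 1:
            raise DesignError(f"spline df must be >= 1, got {self.df}")


class NaturalSpline:
    """A natural cubic spline basis fitted to observed values.

    Evaluating outside the boundary knots extrapolates linearly (the natural
    boundary condition), so second differences vanish there.
    """

    def __init__(self, x: np.ndarray, df: int, knots: np.ndarray | None = None):
        x = np.asarray(x, float)
        if df < 1:
            raise DesignError("natural spline needs df >= 1")
        ux = np.unique(x)
        if ux.size < df + 1:
            raise DesignError(
                f"need at least df+1={df + 1} distinct values for a {df}-df "
                f"natural spline; got {ux.size}"
            )
        self.df = df
        lo, hi = float(ux[0]), float(ux[-1])
        if knots is None:
            if df > 1:
                probs = np.linspace(0, 1, df + 1)[1:-1]
                knots = np.quantile(x, probs, method="linear")
            else:
                knots = np.array([])
        self.boundary = (lo, hi)
        self.interior = np.asarray(knots, float)
        self._t = np.concatenate([[lo] * 4, self.interior, [hi] * 4])
        k_basis = len(self.interior) + 4
        coefs = np.eye(k_basis)
        self._spl = BSpline(self._t, coefs, 3, extrapolate=True)
        # natural constraints: second derivative zero at both boundaries
        d2 = self._spl.derivative(2)(np.array([lo, hi]))  # (2, K)
        # drop the first B-spline column (absorbed by the model intercept),
        # then project the rest onto the constraint null space via QR
        const = d2[:, 1:]  # (2, K-1)
        q, _ = np.linalg.qr(const.T, mode="complete")  # (K-1, K-1)
        self._proj = q[:, 2:]  # (K-1, df)
        if self._proj.shape[1] != df:
            raise DesignError("internal error: natural-spline dimension mismatch")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the df basis columns at x (linear beyond boundaries)."""
        x = np.asarray(x, float)
        lo, hi = self.boundary
        xc = np.clip(x, lo, hi)
        base = self._spl(xc)
        outside = (x < lo) | (x > hi)
        if np.any(outside):
            d1 = self._spl.derivative(1)(np.clip(x[outside], lo, hi))
            base[outside] += d1 * (x[outside] - xc[outside])[:, None]
        return base[:, 1:] @ self._proj


def natural_spline_basis(x: np.ndarray, spec: SplineSpec) -> pd.DataFrame:
    """df-column natural cubic spline basis, columns ``<var>_ns_1..df``."""
    ns = NaturalSpline(np.asarray(x, float), spec.df)
    mat = ns(np.asarray(x, float))
    cols = [f"{spec.variable}_ns_{j + 1}" for j in range(spec.df)]
    return pd.DataFrame(mat, columns=cols)


def weekday_dummies(dates: pd.DatetimeIndex, weekday_only: bool = True) -> pd.DataFrame:
    """Reference-coded day-of-week dummies, Monday as reference.

    Columns follow the day set actually observed: a weekday-only panel gives
    4 columns (Tue-Fri), a full-week panel 6 (Tue-Sun).
    """
    dates = pd.DatetimeIndex(dates)
    dow = dates.dayofweek.to_numpy()
    if weekday_only and np.any(dow >= 5):
        bad = dates[dow >= 5][0].date()
        raise DesignError(f"weekend date {bad} in a weekday-only design")
    observed = sorted(set(dow.tolist()) - {0})
    out = {}
    for d in observed:
        out[f"dow_{WEEKDAY_NAMES[d]}"] = (dow == d).astype(float)
    return pd.DataFrame(out, index=range(len(dates)))


@dataclass
class DesignMatrices:
    """Aligned fixed-effect matrices and response for one model fit.

    ``X``: labelled count-part design (first column ``const``);
    ``Z``: zero-part design (intercept-only by default);
    ``y``: outcome counts; ``groups``: integer unit codes per row;
    ``unit_ids``: code -> unit_id; ``row_index``: (unit_id, date) per row.
    """

    X: pd.DataFrame
    Z: pd.DataFrame
    y: np.ndarray
    groups: np.ndarray
    unit_ids: np.ndarray
    row_index: pd.DataFrame
    pollutant: str
    lag: LagSpec
    outcome_group: str
    age_band: str
    co_pollutant: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def to_csv(self, path) -> None:
        """Export the labelled design for external cross-checking."""
        out = self.row_index.copy()
        out["y"] = self.y
        out = pd.concat([out.reset_index(drop=True), self.X.reset_index(drop=True)], axis=1)
        out.to_csv(path, index=False, float_format="%.12g")


def check_full_rank(X: pd.DataFrame, tol: float = 1e-8) -> None:
    """Raise DesignError naming dependent columns if X is rank deficient."""
    A = X.to_numpy(float)
    scale = np.linalg.norm(A, axis=0)
    scale[scale == 0] = 1.0
    s = np.linalg.svd(A / scale, compute_uv=False)
    if s[-1] / s[0] < tol:
        # identify offending columns by pivoted QR
        _, r, piv = _pivoted_qr(A / scale, pivoting=True, mode="economic")
        diag = np.abs(np.diag(r))
        rank = int(np.sum(diag > diag[0] * tol))
        bad = [X.columns[j] for j in piv[rank:]]
        raise DesignError(
            f"design is rank deficient (cond {s[0] / s[-1]:.2e}); "
            f"dependent column(s): {bad}"
        )


def trend_df_for(start, end, per_year: float = 6.0) -> int:
    """Trend-spline df: 6 per study year, rounded (30 for a 5-year study)."""
    years = (pd.Timestamp(end) - pd.Timestamp(start)).days / 365.25
    return max(1, int(round(per_year * years)))


def build_design(
    panel: PanelDataset,
    decomposed: DecomposedExposure,
    lag: LagSpec,
    outcome_group: str,
    age_band: str,
    co_pollutant: DecomposedExposure | None = None,
    co_decomposed: DecomposedExposure | None = None,
    temp_df: int = 3,
    hum_df: int = 3,
    trend_per_year: float = 6.0,
    zero_mirrors_count: bool = False,
    rank_check: bool = True,
) -> DesignMatrices:
    """Assemble the labelled design for one pollutant/outcome/age/lag cell.

    One row per (unit, weekday) with a complete lag history.  Spline bases
    are built from the pooled observed covariate values of the retained
    rows; the trend basis runs over the sequential calendar-day index.
    """
    co = co_pollutant if co_pollutant is not None else co_decomposed
    ycol = count_column(outcome_group, age_band)
    if ycol not in panel.daily.columns:
        raise DesignError(
            f"no counts for outcome {outcome_group!r} x age band {age_band!r} "
            f"(column {ycol!r} missing)"
        )

    lagged = apply_lag(decomposed.deviation, lag)  # (date x unit)
    lag_long = lagged.stack(future_stack=True).rename("short")  # type: ignore[arg-type]

    daily = panel.daily.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    is_wd = daily["date"].dt.dayofweek < 5
    rows = daily.loc[is_wd, ["unit_id", "date", "temperature", "humidity", ycol]].copy()
    key = pd.MultiIndex.from_frame(rows[["date", "unit_id"]])
    rows["short"] = lag_long.reindex(key).to_numpy()
    rows["long"] = decomposed.unit_mean.reindex(rows["unit_id"]).to_numpy()
    if co is not None:
        co_lagged = apply_lag(co.deviation, lag).stack(future_stack=True)  # type: ignore[arg-type]
        rows["co_short"] = co_lagged.reindex(key).to_numpy()
        rows["co_long"] = co.unit_mean.reindex(rows["unit_id"]).to_numpy()

    rows = rows.dropna(subset=["short"] + (["co_short"] if co is not None else []))
    rows = rows.sort_values(["unit_id", "date"]).reset_index(drop=True)
    if len(rows) == 0:
        raise DesignError("no rows left after lag trimming")
    if rows[ycol].isna().any():
        raise DesignError("missing counts on weekday rows")

    units = panel.units.set_index("unit_id")
    all_days = pd.date_range(panel.study_start, panel.study_end, freq="D")
    day_index = pd.Series(np.arange(len(all_days)), index=all_days)

    pname = decomposed.pollutant
    X = pd.DataFrame({"const": np.ones(len(rows))})
    X[f"{pname}_short"] = rows["short"].to_numpy()
    X[f"{pname}_long"] = rows["long"].to_numpy()
    if co is not None:
        X[f"{co.pollutant}_short"] = rows["co_short"].to_numpy()
        X[f"{co.pollutant}_long"] = rows["co_long"].to_numpy()
    X = pd.concat(
        [
            X,
            natural_spline_basis(rows["temperature"].to_numpy(), SplineSpec("temp", temp_df)),
            natural_spline_basis(rows["humidity"].to_numpy(), SplineSpec("hum", hum_df)),
            natural_spline_basis(
                day_index.reindex(rows["date"]).to_numpy(),
                SplineSpec("trend", trend_df_for(panel.study_start, panel.study_end, trend_per_year)),
            ),
            weekday_dummies(pd.DatetimeIndex(rows["date"])),
        ],
        axis=1,
    )
    X["pct_elderly"] = units["pct_elderly"].reindex(rows["unit_id"]).to_numpy()
    X["deprivation"] = units["deprivation"].reindex(rows["unit_id"]).to_numpy()

    if X.columns.duplicated().any():
        raise DesignError(f"duplicate design labels: {X.columns[X.columns.duplicated()]}")
    if rank_check:
        check_full_rank(X)

    Z = X.copy() if zero_mirrors_count else pd.DataFrame({"const": np.ones(len(rows))})

    unit_ids, groups = np.unique(rows["unit_id"].to_numpy(), return_inverse=True)
    return DesignMatrices(
        X=X,
        Z=Z,
        y=rows[ycol].to_numpy(float).astype(np.int64),
        groups=groups.astype(np.int64),
        unit_ids=unit_ids,
        row_index=rows[["unit_id", "date"]],
        pollutant=pname,
        lag=lag,
        outcome_group=outcome_group,
        age_band=age_band,
        co_pollutant=None if co is None else co.pollutant,
    )
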