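"""Exposure decomposition, lags and IQR scaling.

Each pollutant series is split into a long-term (spatial) and a short-term
(temporal) component::

    X_it = Xbar_i + D_it

where ``Xbar_i`` is unit *i*'s mean concentration over the whole study
period (between-unit contrast, the "long-term" model term) and
``D_it = X_it - Xbar_i`` is the daily deviation (within-unit contrast, the
"short-term" term).  The decomposition is an exact additive identity and is
computed over ALL calendar days -- lagged deviations need weekend exposure
values even though outcomes exist only on weekdays.

Effects downstream are reported per interquartile range: the short-term
term is scaled by the IQR of the daily area-average concentration series
(temporal IQR), the long-term term by the IQR of the per-unit study-period
means (spatial IQR).  The quantile convention is linear interpolation
between order statistics, pinned here in :func:`iqr` and used everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AirPanelError, ConfigError
from .panel_io import POLLUTANTS, PanelDataset

LAG_KINDS = ("lag0", "lag1", "lag2", "week_avg")


@dataclass(frozen=True)
class LagSpec:
    """Exposure lag: same day, 1 or 2 days before, or the 7-day average
    over the index day and the six preceding calendar days (lag 0-6).

    ``calendar_days=False`` switches to weekday-only shifting (a Monday's
    lag 1 is the previous Friday), provided as a sensitivity variant; the
    calendar-day convention is the default because pollution exists on
    weekends too.
    """

    kind: str = "lag0"
    calendar_days: bool = True

    def __post_init__(self) -> None:
        if self.kind not in LAG_KINDS:
            raise ConfigError(f"unknown lag kind {self.kind!r}; valid: {LAG_KINDS}")

    @property
    def label(self) -> str:
        return self.kind


@dataclass
class DecomposedExposure:
    """Long-term unit means and daily deviations for one pollutant.

    ``unit_mean`` is indexed by unit_id; ``deviation`` is a dense
    (date x unit_id) frame over every calendar day of the study.
    """

    pollutant: str
    unit_mean: pd.Series
    deviation: pd.DataFrame


@dataclass
class IQRSet:
    """Temporal and spatial interquartile ranges for one pollutant (ug/m3)."""

    pollutant: str
    temporal_iqr: float
    spatial_iqr: float


def quantile(values: np.ndarray, q: float) -> float:
    """The package-wide quantile convention: linear interpolation between
    order statistics (numpy's ``method='linear'``)."""
    return float(np.percentile(np.asarray(values, float), 100 * q, method="linear"))


def iqr(values: np.ndarray) -> float:
    """Q3 - Q1 under the pinned linear-interpolation convention."""
    values = np.asarray(values, float)
    if values.size < 4:
        raise AirPanelError(f"need >= 4 values for an IQR, got {values.size}")
    return quantile(values, 0.75) - quantile(values, 0.25)


def decompose(panel: PanelDataset, pollutant: str) -> DecomposedExposure:
    """Split one pollutant into unit means and daily deviations.

    Means are taken over all calendar days in the study period.  The result
    satisfies ``unit_mean[i] + deviation[t, i] == X_it`` exactly and each
    unit's deviations average to zero (within float round-off).
    """
    if pollutant not in POLLUTANTS:
        raise AirPanelError(
            f"unknown pollutant {pollutant!r}; valid labels: {list(POLLUTANTS)}"
        )
    wide = panel.daily.pivot(index="date", columns="unit_id", values=pollutant)
    wide = wide.sort_index()
    unit_mean = wide.mean(axis=0)
    deviation = wide - unit_mean
    return DecomposedExposure(pollutant=pollutant, unit_mean=unit_mean, deviation=deviation)


def _check_consecutive(index: pd.DatetimeIndex) -> None:
    if len(index) > 1:
        deltas = np.diff(index.to_numpy()).astype("timedelta64[D]").astype(int)
        if np.any(deltas != 1):
            raise AirPanelError("lagging requires a consecutive calendar-day index")


def apply_lag(deviation: pd.DataFrame | pd.Series, spec: LagSpec) -> pd.DataFrame | pd.Series:
    """Shift a deviation series/frame (indexed by consecutive calendar dates).

    ``lag k`` moves values k days forward; ``week_avg`` is the running mean
    of the index day and the six preceding days.  Dates without a complete
    lag history become NaN -- the design builder drops those outcome rows.

    With ``calendar_days=False`` the same shifts are applied within the
    weekday-only sub-series (sensitivity convention).
    """
    obj = deviation
    idx = pd.DatetimeIndex(obj.index)
    if spec.calendar_days:
        _check_consecutive(idx)
        work = obj
    else:
        work = obj.loc[idx.dayofweek < 5]

    if spec.kind == "lag0":
        out = work.copy()
    elif spec.kind == "lag1":
        out = work.shift(1)
    elif spec.kind == "lag2":
        out = work.shift(2)
    else:  # week_avg: mean over the index day and the 6 preceding days
        out = work.rolling(window=7, min_periods=7).mean()

    if not spec.calendar_days:
        out = out.reindex(obj.index)
    return out


def area_average(panel: PanelDataset, column: str) -> pd.Series:
    """Per-day unweighted mean of a daily column over units."""
    return panel.daily.groupby("date")[column].mean().sort_index()


def compute_iqrs(panel: PanelDataset, pollutant: str) -> IQRSet:
    """Temporal and spatial IQRs for one pollutant.

    temporal: IQR of the daily area-average concentration series;
    spatial: IQR of the per-unit study-period mean concentrations.
    """
    dec = decompose(panel, pollutant)
    daily_avg = area_average(panel, pollutant)
    return IQRSet(
        pollutant=pollutant,
        temporal_iqr=iqr(daily_avg.to_numpy()),
        spatial_iqr=iqr(dec.unit_mean.to_numpy()),
    )


def iqr_table(panel: PanelDataset) -> pd.DataFrame:
    """Temporal/spatial IQRs for all pollutants, as a tidy frame."""
    rows = []
    for p in POLLUTANTS:
        s = compute_iqrs(panel, p)
        rows.append({"pollutant": p, "temporal_iqr": s.temporal_iqr, "spatial_iqr": s.spatial_iqr})
    return pd.DataFrame(rows)
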