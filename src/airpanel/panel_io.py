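"""Panel data model and CSV round-trip.

The interchange object for the whole pipeline is :class:`PanelDataset`: a
dense (spatial unit x calendar day) grid of pollutant exposures and
meteorology, with outcome counts present on weekdays only, plus one row of
time-invariant covariates per unit (percentage of elderly residents and a
deprivation score).

On disk a panel is two RFC-4180 CSV files:

``units.csv``
    one row per unit: ``unit_id, pct_elderly, deprivation``
``daily.csv``
    one row per (unit, calendar day): ``unit_id, date`` (ISO-8601),
    pollutant columns (``no2, pm10, pm25, o3``, ug/m3), ``temperature`` (C),
    ``humidity`` (%), and one ``count__<group>__<age>`` column per outcome
    group x age band.  Count cells are empty on weekends (missing, never 0 --
    a 0 is a legitimate observed count in a zero-inflated model).

Weekdays are Monday-Friday; public holidays are treated as ordinary weekdays.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import IntegrityError, SchemaError

#: canonical pollutant column names (ug/m3; o3 is the 8-h daily maximum,
#: the others 24-h means)
POLLUTANTS: tuple[str, ...] = ("no2", "pm10", "pm25", "o3")

#: meteorology column names
METEO: tuple[str, ...] = ("temperature", "humidity")

_UNIT_COLS = ("unit_id", "pct_elderly", "deprivation")
_DAILY_BASE_COLS = ("unit_id", "date") + POLLUTANTS + METEO


def count_column(outcome_group: str, age_band: str) -> str:
    """Name of the daily-count column for one outcome group x age band."""
    return f"count__{outcome_group}__{age_band}"


def n_weekdays(start: date, end: date) -> int:
    """Number of Monday-Friday dates in the closed interval [start, end]."""
    return int(np.busday_count(start, end) + np.is_busday(end))


@dataclass
class PanelDataset:
    """Dense (unit x day) panel of exposures, meteorology and counts.

    Attributes
    ----------
    units : pd.DataFrame
        One row per unit, columns ``unit_id, pct_elderly, deprivation``.
    daily : pd.DataFrame
        One row per (unit, calendar day); see module docstring for columns.
        Sorted by (unit_id, date).
    study_start, study_end : datetime.date
        Closed study interval; the daily grid covers every calendar day.
    age_bands, outcome_groups : tuple of str
        Labels addressing the ``count__`` columns.
    true_params : dict | None
        Attached by the synthetic generator (generating parameters, for
        recovery tests); not serialized by :func:`write_panel`.
    """

    units: pd.DataFrame
    daily: pd.DataFrame
    study_start: date
    study_end: date
    age_bands: tuple[str, ...]
    outcome_groups: tuple[str, ...]
    true_params: dict | None = field(default=None, compare=False)

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.study_start, self.study_end, freq="D")

    @property
    def count_columns(self) -> list[str]:
        return [count_column(g, a) for g in self.outcome_groups for a in self.age_bands]

    def copy(self) -> "PanelDataset":
        return dataclasses.replace(
            self, units=self.units.copy(), daily=self.daily.copy()
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PanelDataset):
            return NotImplemented
        return panels_equal(self, other, tol=0.0)


def panels_equal(a: PanelDataset, b: PanelDataset, tol: float = 1e-9) -> bool:
    """Value equality of two panels; float columns compared within ``tol``."""
    if (
        a.study_start != b.study_start
        or a.study_end != b.study_end
        or a.age_bands != b.age_bands
        or a.outcome_groups != b.outcome_groups
    ):
        return False
    ua = a.units.sort_values("unit_id").reset_index(drop=True)
    ub = b.units.sort_values("unit_id").reset_index(drop=True)
    da = a.daily.sort_values(["unit_id", "date"]).reset_index(drop=True)
    db = b.daily.sort_values(["unit_id", "date"]).reset_index(drop=True)
    for fa, fb in ((ua, ub), (da, db)):
        if list(fa.columns) != list(fb.columns) or len(fa) != len(fb):
            return False
        for col in fa.columns:
            xa, xb = fa[col], fb[col]
            if pd.api.types.is_float_dtype(xa) or pd.api.types.is_float_dtype(xb):
                va, vb = xa.to_numpy(float), xb.to_numpy(float)
                both_nan = np.isnan(va) & np.isnan(vb)
                if not np.all(both_nan | (np.abs(va - vb) <= tol)):
                    return False
            else:
                if not xa.equals(xb):
                    return False
    return True


@dataclass
class PanelSchema:
    """Column naming and label configuration for :func:`load_panel`.

    Defaults match the canonical on-disk layout; ``column_map`` renames
    source columns to canonical names (``{"NO2_ugm3": "no2", ...}``).
    """

    age_bands: tuple[str, ...] = ("all_ages",)
    outcome_groups: tuple[str, ...] = ("respiratory",)
    column_map: dict[str, str] = field(default_factory=dict)
    weekday_only: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelSchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise SchemaError(f"unknown schema keys: {sorted(bad)}")
        if "age_bands" in raw:
            raw["age_bands"] = tuple(raw["age_bands"])
        if "outcome_groups" in raw:
            raw["outcome_groups"] = tuple(raw["outcome_groups"])
        return cls(**raw)


def validate_panel(ds: PanelDataset) -> None:
    """Check every panel invariant; raise SchemaError/IntegrityError."""
    units, daily = ds.units, ds.daily
    if len(units) == 0:
        raise IntegrityError("panel has no units (degenerate panel rejected)")
    for col in _UNIT_COLS:
        if col not in units.columns:
            raise SchemaError(f"units table missing column {col!r}")
    for col in _DAILY_BASE_COLS:
        if col not in daily.columns:
            raise SchemaError(f"daily table missing column {col!r}")
    for col in ds.count_columns:
        if col not in daily.columns:
            raise SchemaError(f"daily table missing count column {col!r}")

    if units["unit_id"].duplicated().any():
        dup = units.loc[units["unit_id"].duplicated(), "unit_id"].iloc[0]
        raise IntegrityError(f"duplicate unit_id {dup!r} in units table")
    pe = units["pct_elderly"].to_numpy(float)
    if np.any((pe < 0) | (pe > 100)):
        raise IntegrityError("pct_elderly outside [0, 100]")

    extra = set(daily["unit_id"]) - set(units["unit_id"])
    if extra:
        raise IntegrityError(
            f"daily table references unit(s) absent from units table: {sorted(extra)[:5]}"
        )

    if daily.duplicated(subset=["unit_id", "date"]).any():
        row = daily[daily.duplicated(subset=["unit_id", "date"])].iloc[0]
        raise IntegrityError(
            f"duplicate (unit, date) row: ({row['unit_id']!r}, {row['date']})"
        )

    dts = pd.to_datetime(daily["date"])
    expected = pd.date_range(ds.study_start, ds.study_end, freq="D")
    n_expected = len(expected) * len(units)
    if len(daily) != n_expected:
        raise IntegrityError(
            f"daily grid not dense: {len(daily)} rows, expected "
            f"{len(units)} units x {len(expected)} days = {n_expected}"
        )

    for col in POLLUTANTS:
        v = daily[col].to_numpy(float)
        if np.any(~np.isfinite(v)):
            raise IntegrityError(f"missing/non-finite values in exposure column {col!r}")
        if np.any(v < 0):
            raise IntegrityError(f"negative concentration in column {col!r}")
    hum = daily["humidity"].to_numpy(float)
    if np.any(~np.isfinite(hum)) or np.any((hum < 0) | (hum > 100)):
        raise IntegrityError("humidity outside [0, 100] or missing")
    if np.any(~np.isfinite(daily["temperature"].to_numpy(float))):
        raise IntegrityError("missing temperature values")

    is_weekday = dts.dt.dayofweek.to_numpy() < 5
    for col in ds.count_columns:
        v = daily[col].to_numpy(float)
        on_wd, on_we = v[is_weekday], v[~is_weekday]
        if np.any(~np.isnan(on_we)):
            raise IntegrityError(
                f"count column {col!r} has values on weekend dates "
                "(counts are defined for weekdays only)"
            )
        if np.any(np.isnan(on_wd)):
            raise IntegrityError(f"count column {col!r} missing on a weekday")
        if np.any(on_wd < 0) or np.any(on_wd != np.round(on_wd)):
            raise IntegrityError(f"count column {col!r} not a non-negative integer")

    wd_per_unit = n_weekdays(ds.study_start, ds.study_end)
    counts = daily.loc[is_weekday].groupby("unit_id").size()
    if not (counts == wd_per_unit).all():
        bad = counts[counts != wd_per_unit].index[0]
        raise IntegrityError(
            f"unit {bad!r} has {counts[bad]} weekday rows, expected {wd_per_unit}"
        )


def load_panel(
    units_path: str | Path,
    daily_path: str | Path,
    schema: PanelSchema | None = None,
) -> PanelDataset:
    """Read and validate a panel from its two CSV files.

    Raises SchemaError for missing columns, IntegrityError for invariant
    violations (duplicate unit-days, weekend counts, sparse grids...).
    """
    schema = schema or PanelSchema()
    units = pd.read_csv(units_path).rename(columns=schema.column_map)
    daily = pd.read_csv(daily_path).rename(columns=schema.column_map)
    if "date" not in daily.columns:
        raise SchemaError("daily table missing column 'date'")
    daily["date"] = pd.to_datetime(daily["date"], format="ISO8601")
    if "unit_id" in units.columns:
        units["unit_id"] = units["unit_id"].astype(str)
    if "unit_id" in daily.columns:
        daily["unit_id"] = daily["unit_id"].astype(str)
    units = units.sort_values("unit_id").reset_index(drop=True)
    daily = daily.sort_values(["unit_id", "date"]).reset_index(drop=True)

    start, end = daily["date"].min().date(), daily["date"].max().date()
    count_cols = [c for c in daily.columns if c.startswith("count__")]
    groups, bands = [], []
    for c in count_cols:
        try:
            _, g, a = c.split("__")
        except ValueError as exc:
            raise SchemaError(f"malformed count column name {c!r}") from exc
        if g not in groups:
            groups.append(g)
        if a not in bands:
            bands.append(a)
    ds = PanelDataset(
        units=units,
        daily=daily,
        study_start=start,
        study_end=end,
        age_bands=tuple(bands) or schema.age_bands,
        outcome_groups=tuple(groups) or schema.outcome_groups,
    )
    validate_panel(ds)
    return ds


def write_panel(ds: PanelDataset, units_path: str | Path, daily_path: str | Path) -> None:
    """Write a validated panel to two CSV files (round-trips via load_panel)."""
    validate_panel(ds)
    units_path, daily_path = Path(units_path), Path(daily_path)
    ds.units.to_csv(units_path, index=False, float_format="%.12g")
    out = ds.daily.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    for col in ds.count_columns:
        # integer counts with weekend blanks -> pandas nullable Int64
        out[col] = out[col].astype("Int64")
    out.to_csv(daily_path, index=False, float_format="%.12g")
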