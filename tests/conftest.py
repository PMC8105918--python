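import dataclasses

import numpy as np
import pandas as pd
import pytest

import airpanel as ap


def make_tiny_panel(n_units=2, n_days=28, start="2012-01-02", seed=0):
    """Hand-built dense panel, independent of the package's generator."""
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=n_days, freq="D")
    units = pd.DataFrame(
        {
            "unit_id": [f"u{j}" for j in range(n_units)],
            "pct_elderly": np.linspace(5, 20, n_units),
            "deprivation": 25 + 15 * np.sin(1.0 + np.arange(n_units)),
        }
    )
    rows = []
    for j in range(n_units):
        for t, d in enumerate(dates):
            is_wd = d.dayofweek < 5
            rows.append(
                {
                    "unit_id": f"u{j}",
                    "date": d,
                    "no2": 40 + 2 * j + 5 * np.sin(t / 3) + rng.normal(0, 1),
                    "pm10": 20 + j + 3 * np.sin(t / 4) + rng.normal(0, 0.5),
                    "pm25": 15 + 0.5 * j + 2 * np.sin(t / 4) + rng.normal(0, 0.5),
                    "o3": 50 - j + 8 * np.cos(t / 5) + rng.normal(0, 1),
                    "temperature": 10 + 5 * np.sin(t / 6) + rng.normal(0, 1),
                    "humidity": float(np.clip(75 + rng.normal(0, 5), 0, 100)),
                    "count__respiratory__all_ages": float(rng.poisson(2.0)) if is_wd else np.nan,
                }
            )
    daily = pd.DataFrame(rows)
    return ap.PanelDataset(
        units=units,
        daily=daily,
        study_start=dates[0].date(),
        study_end=dates[-1].date(),
        age_bands=("all_ages",),
        outcome_groups=("respiratory",),
    )


@pytest.fixture
def tiny_panel():
    return make_tiny_panel()


def small_study_config(n_units=15, months=6, seed=5, **param_overrides):
    """Desk preset shrunk for fast unit tests (trend df follows the span)."""
    cfg = ap.load_preset("desk")
    end = pd.Timestamp("2012-01-02") + pd.Timedelta(days=int(30.44 * months))
    trend_df = max(1, round(6 * (end - pd.Timestamp("2012-01-02")).days / 365.25))
    params = cfg.outcomes[("asthma_copd_urti", "all_ages")]
    overrides = dict(param_overrides)
    overrides.setdefault("trend", (0.03, -0.02, 0.04, -0.03, 0.02, -0.01)[:trend_df])
    params = dataclasses.replace(params, **overrides)
    return dataclasses.replace(
        cfg,
        n_units=n_units,
        end=end.date(),
        seed=seed,
        outcomes={("asthma_copd_urti", "all_ages"): params},
    )


@pytest.fixture(scope="session")
def desk_small_panel():
    """15 units x ~6 months, shared across fitting tests."""
    return ap.generate_study(small_study_config())


@pytest.fixture(scope="session")
def desk_small_design(desk_small_panel):
    panel = desk_small_panel
    return ap.build_design(
        panel,
        ap.decompose(panel, "pm10"),
        ap.LagSpec("lag0"),
        "asthma_copd_urti",
        "all_ages",
    )


@pytest.fixture(scope="session")
def desk_small_fit(desk_small_design):
    return ap.fit_zinb_mixed(ap.ZINBMixedSpec(design=desk_small_design))


def make_toy_design(n_units=3, n_days=5, seed=7):
    """Small unstructured design for direct likelihood-level tests."""
    rng = np.random.default_rng(seed)
    n = n_units * n_days
    X = pd.DataFrame({"const": np.ones(n), "x1": rng.normal(size=n)})
    groups = np.repeat(np.arange(n_units), n_days)
    y = rng.poisson(1.5, n)
    y[::4] = 0
    return ap.DesignMatrices(
        X=X,
        Z=pd.DataFrame({"const": np.ones(n)}),
        y=y,
        groups=groups,
        unit_ids=np.array([f"u{j}" for j in range(n_units)]),
        row_index=pd.DataFrame({"unit_id": groups, "date": range(n)}),
        pollutant="pm10",
        lag=ap.LagSpec("lag0"),
        outcome_group="g",
        age_band="a",
    )


@pytest.fixture
def toy_design():
    return make_toy_design()
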