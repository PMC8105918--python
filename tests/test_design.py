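import dataclasses

import numpy as np
import pandas as pd
import pytest

import airpanel as ap
from airpanel.design import check_full_rank, trend_df_for

from conftest import make_tiny_panel


def deboor_bspline_design(x, interior, lo, hi, degree=3):
    """Independent cubic B-spline design matrix via the raw de Boor
    recursion (test-only oracle, no scipy)."""
    t = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    n_basis = len(t) - degree - 1
    x = np.asarray(x, float)
    B = np.zeros((len(x), len(t) - 1))
    for i in range(len(t) - 1):
        B[:, i] = np.where((x >= t[i]) & (x < t[i + 1]), 1.0, 0.0)
    B[x == hi, np.searchsorted(t, hi, side="left") - 1] = 1.0
    for k in range(1, degree + 1):
        Bn = np.zeros((len(x), len(t) - k - 1))
        for i in range(len(t) - k - 1):
            left = np.zeros(len(x))
            if t[i + k] > t[i]:
                left = (x - t[i]) / (t[i + k] - t[i]) * B[:, i]
            right = np.zeros(len(x))
            if t[i + k + 1] > t[i + 1]:
                right = (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * B[:, i + 1]
            Bn[:, i] = left + right
        B = Bn
    return B[:, :n_basis]


class TestNaturalSpline:
    def test_linear_functions_in_span(self):
        x = np.linspace(0, 100, 150)
        B = ap.natural_spline_basis(x, ap.SplineSpec("v", 3)).to_numpy()
        A = np.column_stack([np.ones_like(x), B])
        y = 2 * x + 1
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert np.abs(A @ coef - y).max() < 1e-8

    def test_natural_boundary_condition(self):
        """Second differences vanish beyond the boundary knots."""
        ns = ap.NaturalSpline(np.linspace(0, 10, 80), df=4)
        for x0 in (-8.0, 14.0):
            pts = ns(np.array([x0 - 0.5, x0, x0 + 0.5]))
            d2 = pts[0] - 2 * pts[1] + pts[2]
            assert np.abs(d2).max() < 1e-6

    def test_column_space_matches_deboor_oracle(self):
        """Our natural basis lies in the independent de Boor B-spline space
        and satisfies the boundary constraints there."""
        x = np.linspace(0, 100, 400)
        df = 3
        ns = ap.NaturalSpline(x, df)
        ours = ns(x)
        oracle = deboor_bspline_design(x, ns.interior, *ns.boundary)
        # projection of each of our columns onto the oracle space
        coef, *_ = np.linalg.lstsq(oracle, ours, rcond=None)
        resid = ours - oracle @ coef
        assert np.abs(resid).max() < 1e-8

    def test_too_few_distinct_values(self):
        with pytest.raises(ap.DesignError):
            ap.natural_spline_basis(np.array([1.0, 1.0, 2.0]), ap.SplineSpec("v", 3))

    def test_df_columns(self):
        x = np.linspace(0, 1, 50)
        for df in (1, 2, 3, 6):
            assert ap.natural_spline_basis(x, ap.SplineSpec("v", df)).shape == (50, df)


class TestWeekdayDummies:
    def test_reference_coding(self):
        week = pd.date_range("2012-01-02", periods=5, freq="D")  # Mon-Fri
        D = ap.weekday_dummies(week)
        assert list(D.columns) == ["dow_Tue", "dow_Wed", "dow_Thu", "dow_Fri"]
        assert np.allclose(D.to_numpy().sum(axis=1), [0, 1, 1, 1, 1])
        assert np.allclose(np.diag(D.to_numpy()[1:]), 1.0)

    def test_all_mondays_gives_no_columns(self):
        mondays = pd.date_range("2012-01-02", periods=4, freq="7D")
        D = ap.weekday_dummies(mondays)
        assert D.to_numpy().size == 0

    def test_full_week_gives_six_dummies(self):
        week = pd.date_range("2012-01-02", periods=7, freq="D")
        D = ap.weekday_dummies(week, weekday_only=False)
        assert D.shape[1] == 6

    def test_weekend_rejected_in_weekday_mode(self):
        sat = pd.date_range("2012-01-07", periods=1, freq="D")
        with pytest.raises(ap.DesignError):
            ap.weekday_dummies(sat)


class TestBuildDesign:
    def test_column_layout_and_row_count(self):
        panel = make_tiny_panel(n_units=2, n_days=14)  # 10 weekdays
        dm = ap.build_design(
            panel, ap.decompose(panel, "pm10"), ap.LagSpec("lag0"),
            "respiratory", "all_ages", rank_check=False,
        )
        assert dm.n_obs == 2 * 10
        tdf = trend_df_for(panel.study_start, panel.study_end)
        expected = 1 + 2 + 3 + 3 + tdf + 4 + 2
        assert dm.X.shape[1] == expected
        assert dm.X.columns[0] == "const"
        assert {"pm10_short", "pm10_long", "pct_elderly", "deprivation"} <= set(dm.X.columns)

    def test_lag_trimming_drops_incomplete_history(self):
        panel = make_tiny_panel(n_units=2, n_days=14)
        d0 = ap.build_design(panel, ap.decompose(panel, "pm10"), ap.LagSpec("lag0"),
                             "respiratory", "all_ages", rank_check=False)
        d1 = ap.build_design(panel, ap.decompose(panel, "pm10"), ap.LagSpec("lag1"),
                             "respiratory", "all_ages", rank_check=False)
        dw = ap.build_design(panel, ap.decompose(panel, "pm10"), ap.LagSpec("week_avg"),
                             "respiratory", "all_ages", rank_check=False)
        # lag1: only the very first calendar day lacks history -> first Monday
        assert d0.n_obs - d1.n_obs == 2
        # week_avg: first 6 calendar days lack history -> Mon-Fri of week 1
        assert d0.n_obs - dw.n_obs == 2 * 5

    def test_co_pollutant_adds_exactly_two_columns(self):
        panel = make_tiny_panel(n_units=2, n_days=14)
        dec = ap.decompose(panel, "pm25")
        co = ap.decompose(panel, "no2")
        base = ap.build_design(panel, dec, ap.LagSpec("lag0"), "respiratory", "all_ages",
                               rank_check=False)
        two = ap.build_design(panel, dec, ap.LagSpec("lag0"), "respiratory", "all_ages",
                              co_pollutant=co, rank_check=False)
        assert two.X.shape[1] - base.X.shape[1] == 2
        assert {"no2_short", "no2_long"} <= set(two.X.columns)

    def test_missing_outcome_cell_rejected(self):
        panel = make_tiny_panel()
        with pytest.raises(ap.DesignError, match="count__respiratory__0-17"):
            ap.build_design(panel, ap.decompose(panel, "pm10"), ap.LagSpec("lag0"),
                            "respiratory", "0-17")

    def test_rank_deficiency_names_columns(self):
        X = pd.DataFrame(
            {
                "const": np.ones(30),
                "a": np.arange(30.0),
                "b": 2 * np.arange(30.0),
            }
        )
        with pytest.raises(ap.DesignError, match="rank deficient"):
            check_full_rank(X)

    def test_trend_df_rule(self):
        from datetime import date

        assert trend_df_for(date(2009, 1, 1), date(2013, 12, 31)) == 30
        assert trend_df_for(date(2012, 1, 2), date(2012, 12, 28)) == 6

    def test_centering_reparameterization_invariance(self):
        """Shifting long-term means by -c and deviations by +c leaves the
        fitted short-term coefficient unchanged (Poisson fixed-effects fit)."""
        import statsmodels.api as sm

        panel = make_tiny_panel(n_units=4, n_days=42)
        dec = ap.decompose(panel, "pm10")
        c = 5.0
        dec2 = ap.DecomposedExposure(
            pollutant="pm10", unit_mean=dec.unit_mean - c, deviation=dec.deviation + c
        )
        coefs = []
        for d in (dec, dec2):
            dm = ap.build_design(panel, d, ap.LagSpec("lag0"), "respiratory", "all_ages")
            res = sm.GLM(dm.y, dm.X.to_numpy(), family=sm.families.Poisson()).fit()
            coefs.append(pd.Series(res.params, index=dm.X.columns))
        assert coefs[0]["pm10_short"] == pytest.approx(coefs[1]["pm10_short"], abs=1e-6)

    def test_design_export_roundtrip(self, tmp_path):
        panel = make_tiny_panel(n_units=2, n_days=14)
        dm = ap.build_design(panel, ap.decompose(panel, "pm10"), ap.LagSpec("lag0"),
                             "respiratory", "all_ages", rank_check=False)
        path = tmp_path / "design.csv"
        dm.to_csv(path)
        back = pd.read_csv(path)
        assert len(back) == dm.n_obs
        assert set(dm.X.columns) <= set(back.columns)
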