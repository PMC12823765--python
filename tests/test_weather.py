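"""Weather cleaning: bias-corrected gap filling, interpolation, hourly
conversion."""

import math

import numpy as np
import pandas as pd
import pytest

from phenoflex.weather import (daily_to_hourly, fill_gaps_bias_corrected,
                               interpolate_linear, solar_daylength)


def daily_frame(tmin, tmax, start="2000-11-01"):
    n = len(tmin)
    return pd.DataFrame({
        "date": pd.date_range(start, periods=n, freq="D"),
        "tmin": tmin, "tmax": tmax,
    })


class TestGapFilling:
    def make_pair(self, offset=1.5, n=31, gap_at=15):
        rng = np.random.default_rng(0)
        base = 5 + 3 * np.sin(np.arange(n) / 4) + rng.normal(0, 1, n)
        target = daily_frame(base, base + 8.0)
        aux = daily_frame(base + offset, base + 8.0 + offset)
        truth = target.copy()
        target.loc[gap_at, ["tmin", "tmax"]] = np.nan
        return target, aux, truth

    def test_constant_offset_recovers_withheld_truth_exactly(self):
        for c in (-2.0, 0.0, 1.5, 3.5):
            target, aux, truth = self.make_pair(offset=c)
            filled, qc = fill_gaps_bias_corrected(target, aux)
            assert filled.loc[15, "tmin"] == pytest.approx(
                truth.loc[15, "tmin"], abs=1e-9)
            assert filled.loc[15, "tmax"] == pytest.approx(
                truth.loc[15, "tmax"], abs=1e-9)
            assert len(qc) == 2  # tmin and tmax filled independently

    def test_bias_definition(self):
        # aux exceeds target by +2 in the window; aux(gap day) = 10 -> 8
        target = daily_frame([5.0] * 15, [15.0] * 15)
        aux = daily_frame([7.0] * 15, [17.0] * 15)
        aux.loc[7, "tmin"] = 10.0
        target.loc[7, "tmin"] = np.nan
        filled, qc = fill_gaps_bias_corrected(target, aux)
        assert filled.loc[7, "tmin"] == pytest.approx(8.0)
        row = qc[qc["variable"] == "tmin"].iloc[0]
        assert row["bias"] == pytest.approx(2.0)

    def test_fully_observed_is_identity_with_empty_report(self):
        target, aux, _ = self.make_pair()
        target = aux.copy()  # no gaps
        filled, qc = fill_gaps_bias_corrected(target, aux)
        pd.testing.assert_frame_equal(filled, target)
        assert qc.empty

    def test_idempotent(self):
        target, aux, _ = self.make_pair()
        once, _ = fill_gaps_bias_corrected(target, aux)
        twice, qc2 = fill_gaps_bias_corrected(once, aux)
        pd.testing.assert_frame_equal(once, twice)
        assert qc2.empty

    def test_gap_without_shared_days_left_missing_and_flagged(self):
        target = daily_frame([5.0] * 9, [15.0] * 9)
        target.loc[4, "tmin"] = np.nan
        aux = daily_frame([6.0] * 9, [16.0] * 9, start="2001-05-01")  # no overlap
        filled, qc = fill_gaps_bias_corrected(target, aux)
        assert np.isnan(filled.loc[4, "tmin"])
        assert bool(qc.iloc[0]["flagged"]) and not bool(qc.iloc[0]["filled"])

    def test_large_bias_flagged(self):
        target = daily_frame([5.0] * 15, [15.0] * 15)
        aux = daily_frame([10.0] * 15, [20.0] * 15)  # +5 degC bias
        target.loc[7, "tmin"] = np.nan
        filled, qc = fill_gaps_bias_corrected(target, aux)
        assert bool(qc.iloc[0]["flagged"])
        assert filled.loc[7, "tmin"] == pytest.approx(5.0)  # still corrected

    def test_best_aux_station_chosen_by_shared_days(self):
        n = 15
        base = np.linspace(0, 5, n)
        target = daily_frame(base, base + 10)
        target.loc[7, "tmin"] = np.nan
        sparse = daily_frame(base + 9.0, base + 19.0)
        sparse.loc[[0, 1, 2, 3, 4, 9, 10, 11, 12, 13, 14],
                   ["tmin", "tmax"]] = np.nan
        dense = daily_frame(base + 1.0, base + 11.0)
        sparse["station_id"] = "sparse"
        dense["station_id"] = "dense"
        aux = pd.concat([sparse, dense], ignore_index=True)
        filled, qc = fill_gaps_bias_corrected(target, aux)
        assert qc.iloc[0]["station_id"] == "dense"
        assert filled.loc[7, "tmin"] == pytest.approx(base[7], abs=1e-9)

    def test_even_window_rejected(self):
        target, aux, _ = self.make_pair()
        with pytest.raises(ValueError):
            fill_gaps_bias_corrected(target, aux, window_days=14)


class TestInterpolation:
    def test_midpoint(self):
        df = daily_frame([4.0, np.nan, 8.0], [14.0, np.nan, 18.0])
        out, report = interpolate_linear(df)
        assert out.loc[1, "tmin"] == pytest.approx(6.0)
        assert out.loc[1, "tmax"] == pytest.approx(16.0)
        assert report.empty

    def test_multi_day_gap_closed_form(self):
        df = daily_frame([0.0, np.nan, np.nan, 9.0],
                         [10.0, np.nan, np.nan, 19.0])
        out, _ = interpolate_linear(df)
        np.testing.assert_allclose(out["tmin"], [0.0, 3.0, 6.0, 9.0])

    def test_identity_when_no_gaps(self):
        df = daily_frame([1.0, 2.0], [11.0, 12.0])
        out, report = interpolate_linear(df)
        pd.testing.assert_frame_equal(out, df)
        assert report.empty

    def test_edge_gaps_reported_not_filled(self):
        df = daily_frame([np.nan, 2.0, 3.0], [np.nan, 12.0, 13.0])
        out, report = interpolate_linear(df)
        assert np.isnan(out.loc[0, "tmin"])
        assert len(report) == 2

    def test_all_missing_is_an_error(self):
        df = daily_frame([np.nan] * 3, [np.nan] * 3)
        with pytest.raises(ValueError):
            interpolate_linear(df)


class TestSolarGeometry:
    def test_daylength_longer_in_summer_at_midlatitude(self):
        _, _, summer = solar_daylength(40.0, 172)  # late June
        _, _, winter = solar_daylength(40.0, 355)  # late December
        assert summer > winter
        # standard sunrise-equation oracle: cos H = -tan(lat)tan(decl)
        decl = math.radians(-23.44) * math.cos(2 * math.pi * (172 + 10) / 365)
        H = math.acos(-math.tan(math.radians(40.0)) * math.tan(decl))
        assert summer == pytest.approx(2 * math.degrees(H) / 15.0, abs=1e-9)

    def test_equator_always_near_12h(self):
        for doy in (1, 100, 200, 300):
            _, _, dl = solar_daylength(0.0, doy)
            assert dl == pytest.approx(12.0, abs=0.1)

    def test_invalid_latitude(self):
        with pytest.raises(ValueError):
            solar_daylength(100.0, 50)


class TestDailyToHourly:
    def test_constant_day_gives_constant_hours(self):
        df = daily_frame([10.0] * 5, [10.0] * 5)
        hourly = daily_to_hourly(df, latitude=40.0)
        assert len(hourly) == 5 * 24
        np.testing.assert_allclose(hourly["temp"], 10.0)

    def test_extremes_preserved_per_day(self):
        rng = np.random.default_rng(1)
        tmin = rng.uniform(-5, 5, 30)
        tmax = tmin + rng.uniform(5, 15, 30)
        df = daily_frame(tmin, tmax)
        hourly = daily_to_hourly(df, latitude=40.0)
        temps = hourly["temp"].to_numpy().reshape(30, 24)
        for d in range(1, 29):
            # the anchored peak hour reproduces the daily maximum exactly,
            # and the day's envelope is bounded by its own extremes except
            # where the overnight segment heads toward a (colder or much
            # warmer) next-day minimum
            assert temps[d].max() >= tmax[d] - 1e-9
            assert temps[d].max() <= max(tmax[d], tmin[d + 1]) + 1e-6
            assert temps[d].min() >= min(tmin[d], tmin[d + 1]) - 1e-6
            assert tmax[d] in temps[d]

    def test_missing_day_errors_with_date(self):
        df = daily_frame([1.0, np.nan, 3.0], [11.0, 12.0, 13.0])
        with pytest.raises(ValueError, match="2000-11-02"):
            daily_to_hourly(df, latitude=40.0)

    def test_output_shape_and_continuity(self):
        df = daily_frame(np.linspace(0, 4, 10), np.linspace(10, 14, 10))
        hourly = daily_to_hourly(df, latitude=50.0)
        assert len(hourly) == 240
        # continuous across midnight: jumps bounded by the curve's scale
        assert np.abs(np.diff(hourly["temp"].to_numpy())).max() < 6.0
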