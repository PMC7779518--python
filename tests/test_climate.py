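import numpy as np
import pandas as pd
import pytest

from lirype.climate import (
    build_covariate_table,
    derive_climate_variables,
    orient_harshness,
    rolling_mean,
    seasonal_mean_temp,
    split_spatial_temporal,
    spring_onset,
    standardize,
    winter_onset,
)
from lirype.data_model import DailyClimateRecord


def naive_rolling_mean(x, window):
    out = np.full(len(x), np.nan)
    for k in range(window - 1, len(x)):
        out[k] = float(np.mean(x[k - window + 1: k + 1]))
    return out


class TestRollingMean:
    def test_constant_series(self):
        out = rolling_mean(np.full(20, 3.5), 7)
        assert np.allclose(out[6:], 3.5)
        assert np.isnan(out[:6]).all()

    def test_trailing_window_arithmetic(self):
        out = rolling_mean([0, 0, 0, 0, 0, 0, 7], 7)
        assert out[-1] == pytest.approx(1.0)

    def test_matches_naive_oracle(self, rng):
        x = rng.normal(size=200)
        for w in (1, 3, 7, 30):
            got = rolling_mean(x, w)
            want = naive_rolling_mean(x, w)
            assert np.allclose(got[w - 1:], want[w - 1:])

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            rolling_mean([1.0, 2.0], 7)


def scan_onset(snow, window, above):
    """Brute-force day-by-day scan, the independent oracle for onsets."""
    for k in range(window - 1, len(snow)):
        m = float(np.mean(snow[k - window + 1: k + 1]))
        if (m > 1e-9) if above else (abs(m) <= 1e-9):
            return k + 1
    return None


class TestOnsets:
    def test_snow_free_year_clears_at_first_full_window(self):
        assert spring_onset(np.zeros(365)) == 7

    def test_permanent_snow_has_no_spring(self):
        assert spring_onset(np.ones(365)) is None

    def test_bare_autumn_has_no_winter_onset(self):
        assert winter_onset(np.zeros(180)) is None

    def test_snowy_series_onset_at_first_window(self):
        assert winter_onset(np.ones(180)) == 7

    def test_gap_raises(self):
        snow = np.ones(100)
        snow[40] = np.nan
        with pytest.raises(ValueError):
            spring_onset(snow)

    def test_onsets_match_linear_scan_on_synthetic_curves(self, rng):
        # melt curves: declining depth hitting zero mid-series; accumulation mirrored
        for _ in range(200):
            start = rng.uniform(10, 80)
            melt_day = int(rng.integers(20, 300))
            depth = np.clip(start * (1 - np.arange(330) / melt_day), 0, None)
            depth += rng.uniform(0, 0.5) * (rng.random(330) < 0.1)  # late flurries
            assert spring_onset(depth) == scan_onset(depth, 7, above=False)
            accum = depth[::-1].copy()
            assert winter_onset(accum) == scan_onset(accum, 7, above=True)


class TestSeasonalMeanTemp:
    def _series(self, values_by_month, year):
        idx = pd.date_range(f"{year - 1}-10-01", f"{year}-06-30")
        vals = [values_by_month.get(ts.month, 0.0) for ts in idx]
        return pd.Series(vals, index=idx)

    def test_constant_season(self):
        temps = self._series({3: -5.0, 4: -5.0, 5: -5.0}, 2010)
        assert seasonal_mean_temp(temps, "spring", 2010) == pytest.approx(-5.0)

    def test_spring_mean_is_hand_computed(self, rng):
        idx = pd.date_range("2011-03-01", "2011-05-31")
        vals = rng.normal(size=idx.size)
        temps = pd.Series(vals, index=idx)
        assert seasonal_mean_temp(temps, "spring", 2011) == pytest.approx(vals.mean())

    def test_winter_spans_calendar_boundary_weighted_by_days(self):
        # Dec 2009 = -2, Jan/Feb 2010 = -8; DJF mean is the day-count weighted mean
        temps = self._series({12: -2.0, 1: -8.0, 2: -8.0}, 2010)
        want = (31 * -2.0 + 59 * -8.0) / 90
        assert seasonal_mean_temp(temps, "winter", 2010) == pytest.approx(want)

    def test_order_invariance(self, rng):
        idx = pd.date_range("2011-03-01", "2011-05-31")
        vals = rng.normal(size=idx.size)
        a = seasonal_mean_temp(pd.Series(vals, index=idx), "spring", 2011)
        perm = rng.permutation(idx.size)
        b = seasonal_mean_temp(pd.Series(vals[perm], index=idx[perm]), "spring", 2011)
        assert a == pytest.approx(b)

    def test_missing_days_raise(self):
        idx = pd.date_range("2011-03-02", "2011-05-31")  # March 1 missing
        with pytest.raises(ValueError):
            seasonal_mean_temp(pd.Series(0.0, index=idx), "spring", 2011)


class TestSplitSpatialTemporal:
    def test_constant_in_time_gives_zero_anomalies(self):
        v = pd.DataFrame({1: [3.0, 5.0], 2: [3.0, 5.0]}, index=["A", "B"])
        cs, ct = split_spatial_temporal(v, [1, 2])
        assert np.allclose(ct.to_numpy(), 0.0)
        assert list(cs) == [3.0, 5.0]

    def test_two_year_arithmetic(self):
        v = pd.DataFrame({1: [10.0], 2: [14.0]}, index=["A"])
        cs, ct = split_spatial_temporal(v, [1, 2])
        assert cs["A"] == pytest.approx(12.0)
        assert list(ct.loc["A"]) == [-2.0, 2.0]

    def test_anomalies_sum_to_zero_per_transect(self, rng):
        years = list(range(1, 11))
        v = pd.DataFrame(rng.normal(size=(40, 10)), columns=years)
        _, ct = split_spatial_temporal(v, years)
        assert np.abs(ct.sum(axis=1).to_numpy()).max() < 1e-9


class TestStandardize:
    def test_simple_case(self):
        z, (mean, sd) = standardize({"a": 1.0, "b": 2.0, "c": 3.0})
        assert mean == pytest.approx(2.0)
        assert z.mean() == pytest.approx(0.0)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_idempotent(self, rng):
        z1, _ = standardize(rng.normal(3, 7, size=50))
        z2, _ = standardize(z1)
        assert np.allclose(z1, z2, atol=1e-12)

    def test_matches_two_pass_oracle(self, rng):
        x = rng.normal(5, 2, size=100)
        z, (mean, sd) = standardize(x)
        assert mean == pytest.approx(float(np.mean(x)))
        assert sd == pytest.approx(float(np.std(x, ddof=1)))
        assert np.allclose(z, (x - mean) / sd)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            standardize([2.0, 2.0, 2.0])


class TestOrientHarshness:
    def test_spring_onset_effects_are_flipped(self):
        assert orient_harshness("spring_onset", [0.2])[0] == pytest.approx(-0.2)

    def test_temperature_effects_unchanged(self):
        assert orient_harshness("winter_temp", [0.2])[0] == pytest.approx(0.2)

    def test_involution(self, rng):
        x = rng.normal(size=5)
        for var in ("spring_onset", "winter_temp", "spring_temp", "winter_onset"):
            assert np.allclose(orient_harshness(var, orient_harshness(var, x)), x)


class TestDeriveClimateVariables:
    @pytest.fixture()
    def records(self):
        """Two transects, one cold one warm, two analysis years of daily data."""
        recs = []
        for tid, shift in (("W", 6.0), ("C", -2.0)):
            idx = pd.date_range("2009-07-01", "2011-06-30")
            doy = idx.day_of_year.to_numpy()
            anomaly = np.where(idx.year.to_numpy() >= 2011, 1.5, 0.0)  # warm 2011
            temp = shift + anomaly - 11.0 * np.cos(2 * np.pi * (doy - 15) / 365.0)
            snow = np.zeros(idx.size)
            s = 0.0
            for k, tc in enumerate(temp):
                s = max(0.0, s + (0.6 if tc < 0 else -0.5 * tc))
                snow[k] = s
            recs.extend(
                DailyClimateRecord(tid, d.date(), float(tc), float(sn))
                for d, tc, sn in zip(idx, temp, snow)
            )
        return recs

    def test_all_variables_produced_and_ordered(self, records):
        tables = derive_climate_variables(records, [2010, 2011])
        assert set(tables) == {"spring_onset", "spring_temp", "winter_onset", "winter_temp"}
        for var in tables:
            assert tables[var].shape == (2, 2)
        # the cold transect is colder, clears later, snows in earlier
        assert (tables["winter_temp"].loc["C"] < tables["winter_temp"].loc["W"]).all()
        assert (tables["spring_onset"].loc["C"] > tables["spring_onset"].loc["W"]).all()
        assert (tables["winter_onset"].loc["C"] < tables["winter_onset"].loc["W"]).all()

    def test_covariate_table_standardized(self, records):
        tables = derive_climate_variables(records, [2010, 2011])
        table = build_covariate_table(tables["winter_temp"], [2010, 2011], "winter_temp")
        assert abs(table.cs.mean()) < 1e-10
        assert abs(table.ct.mean()) < 1e-10
        assert table.cs.std(ddof=1) == pytest.approx(1.0)
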