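import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from urbanrhythm import activity, rhythm_metrics, solar, synthetic
from urbanrhythm.cdr_io import City
from urbanrhythm.rhythm_metrics import (
    band_average,
    cohort_metrics,
    collapse_band,
    filter_holidays,
    low_activity_period,
    mid_sleep,
    solar_comparison_report,
)


def make_cities():
    return [
        City("west", 42.0, 0.67, -7.8, 300_000, (42.0, -7.8)),
        City("ref", 42.0, 0.67, 0.0, 400_000, (42.0, 0.0)),
        City("east", 42.0, 0.67, 3.0, 200_000, (42.0, 3.0)),
    ]


def timing_frame(rows):
    return pd.DataFrame(rows, columns=["city", "day", "t_F", "t_L"])


class TestCollapse:
    def test_reference_city_unshifted(self):
        timing = timing_frame([("ref", 1, 11.0, 22.0)])
        out = collapse_band(timing, make_cities(), "ref")
        assert out.loc[0, "t_F"] == 11.0 and out.loc[0, "t_L"] == 22.0

    def test_western_city_advanced_by_transit_delay(self):
        timing = timing_frame([("west", 1, 11.0, 22.0)])
        out = collapse_band(timing, make_cities(), "ref")
        assert out.loc[0, "t_L"] == pytest.approx(22.0 - 31.2 / 60.0)
        assert out.loc[0, "t_F"] == pytest.approx(11.0 - 31.2 / 60.0)

    def test_solar_entrained_cities_coincide_after_collapse(self):
        # two cities whose timings differ exactly by their transit delay
        timing = timing_frame(
            [("ref", 1, 11.0, 22.0),
             ("west", 1, 11.0 + 31.2 / 60.0, 22.0 + 31.2 / 60.0),
             ("east", 1, 11.0 - 12.0 / 60.0, 22.0 - 12.0 / 60.0)]
        )
        out = collapse_band(timing, make_cities(), "ref")
        assert out["t_L"].std() == pytest.approx(0.0, abs=1e-12)
        assert out["t_F"].std() == pytest.approx(0.0, abs=1e-12)

    def test_city_without_longitude_dropped(self):
        timing = timing_frame([("ref", 1, 11.0, 22.0), ("ghost", 1, 11.0, 22.0)])
        out = collapse_band(timing, make_cities(), "ref")
        assert out["city"].tolist() == ["ref"]


class TestBandAverage:
    def test_single_city_identity(self):
        out = band_average(timing_frame([("ref", 1, 11.0, 23.0)]))
        assert out.loc[0, "tL_bar"] == 23.0 and out.loc[0, "n_cities"] == 1

    def test_two_city_mean(self):
        out = band_average(
            timing_frame([("a", 1, 11.0, 23.0), ("b", 1, 11.5, 23.5)])
        )
        assert out.loc[0, "tL_bar"] == pytest.approx(23.25)
        assert out.loc[0, "tF_bar"] == pytest.approx(11.25)

    def test_permutation_invariance(self):
        rows = [("a", 1, 11.0, 23.0), ("b", 1, 11.5, 23.5), ("c", 1, 10.5, 22.0)]
        fwd = band_average(timing_frame(rows))
        rev = band_average(timing_frame(rows[::-1]))
        pd.testing.assert_frame_equal(fwd, rev)


class TestHolidayFilter:
    def test_empty_set_is_identity(self):
        series = timing_frame([("a", d, 11.0, 23.0) for d in range(1, 11)])
        pd.testing.assert_frame_equal(filter_holidays(series, set()), series)

    def test_cardinality_after_removal(self):
        series = timing_frame([("a", d, 11.0, 23.0) for d in range(1, 366)])
        out = filter_holidays(series, {1, 359})
        assert len(out) == 363
        assert not out["day"].isin({1, 359}).any()


class TestFormulae:
    @pytest.mark.parametrize("t_l,t_f,expected", [(23.0, 8.0, 9.0), (25.0, 7.0, 6.0)])
    def test_low_activity_period(self, t_l, t_f, expected):
        assert low_activity_period(t_l, t_f) == pytest.approx(expected)

    def test_non_positive_period_rejected(self):
        with pytest.raises(ValueError):
            low_activity_period(27.0, 5.0 - 2.5)

    @pytest.mark.parametrize(
        "t_l,t_f,expected", [(23.0, 8.0, 3.5), (22.0, 6.0, 2.0), (24.5, 8.0, 4.25)]
    )
    def test_mid_sleep(self, t_l, t_f, expected):
        assert mid_sleep(t_l, t_f) == pytest.approx(expected)

    @given(st.floats(17.0, 27.99), st.floats(5.0, 15.99))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_mid_sleep_consistent_with_low_activity_period(self, t_l, t_f):
        t_lca = low_activity_period(t_l, t_f)
        assert mid_sleep(t_l, t_f) == pytest.approx(
            (t_l + t_lca / 2.0 - 24.0) % 24.0, abs=1e-9
        )


def cohort_calls(rows):
    return pd.DataFrame(
        rows, columns=["caller_id", "day", "weekday", "extended_hour"]
    )


def subscribers_frame(rows):
    out = pd.DataFrame(rows, columns=["id", "age", "gender"])
    for col in ("postal_lat", "postal_lon", "tower_lat", "tower_lon"):
        out[col] = 42.0
    out["home_city"] = "c"
    return out


class TestCohortMetrics:
    def test_single_cohort_single_weekday(self):
        # Tuesday night (weekday 1, days 2, 9, ...) and Wednesday morning
        rows = []
        for u in range(60):
            rows.append((f"u{u}", 2, 1, 22.0 + (u % 5) * 0.1))   # Tue night
            rows.append((f"u{u}", 3, 2, 8.0 + (u % 5) * 0.1))    # Wed morning
        subs = subscribers_frame([(f"u{u}", 30, "female") for u in range(60)])
        out = cohort_metrics(cohort_calls(rows), subs,
                             age_bins=[(25, 35)], weekdays=(1,), min_users=50)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["gender"] == "female" and row["weekday"] == 1
        assert row["t_L"] == pytest.approx(22.2, abs=0.05)
        assert row["t_F"] == pytest.approx(8.2, abs=0.05)
        assert row["T_LCA"] == pytest.approx(row["t_F"] + 24 - row["t_L"])
        assert row["t_mid"] == pytest.approx((row["t_L"] + row["t_F"] - 24) / 2)

    def test_small_cohort_suppressed(self):
        rows = [(f"u{u}", 2, 1, 22.0) for u in range(10)]
        rows += [(f"u{u}", 3, 2, 8.0) for u in range(10)]
        subs = subscribers_frame([(f"u{u}", 30, "male") for u in range(10)])
        out = cohort_metrics(cohort_calls(rows), subs,
                             age_bins=[(25, 35)], weekdays=(1,), min_users=50)
        assert out.empty

    def test_gender_and_age_binning(self):
        rows, subs = [], []
        for u in range(120):
            age = 20 if u < 60 else 70
            gender = "female" if u % 2 else "male"
            subs.append((f"u{u}", age, gender))
            rows.append((f"u{u}", 2, 1, 22.0))
            rows.append((f"u{u}", 3, 2, 8.0))
        out = cohort_metrics(cohort_calls(rows), subscribers_frame(subs),
                             age_bins=[(18, 30), (60, 80)], weekdays=(1,),
                             min_users=20)
        assert len(out) == 4
        assert set(zip(out["age_lo"], out["gender"])) == {
            (18, "female"), (18, "male"), (60, "female"), (60, "male")
        }

    def test_mon_thu_pooling(self):
        rows, subs = [], []
        for u in range(60):
            subs.append((f"u{u}", 30, "male"))
            for night in (1, 2):  # Tue and Wed nights
                rows.append((f"u{u}", night + 1, night, 22.0))
                rows.append((f"u{u}", night + 2, night + 1, 8.0))
        pooled = cohort_metrics(cohort_calls(rows), subscribers_frame(subs),
                                age_bins=[(25, 35)], weekdays=(1, 2),
                                min_users=50, pool_mon_thu=True)
        assert len(pooled) == 1 and pooled.iloc[0]["weekday"] == 0


class TestSolarComparison:
    def test_constant_band_series_has_no_activity_extrema(self):
        band = pd.DataFrame(
            {"day": range(1, 366), "tF_bar": 11.0, "tL_bar": 22.0}
        )
        out = solar_comparison_report(band, 40.0, 0.0)
        assert not out["tL_bar_is_min"].any() and not out["tL_bar_is_max"].any()
        assert out["solar_midnight_is_min"].sum() >= 2
        assert out["solar_midnight_is_max"].sum() >= 1

    def test_columns_in_zone_clock_time(self):
        band = pd.DataFrame({"day": [100, 200], "tF_bar": 11.0, "tL_bar": 22.0})
        out = solar_comparison_report(band, 40.0, 0.0)
        assert out["sunrise"].between(4, 9).all()
        assert out["solar_midnight"].between(23, 27).all()


@pytest.fixture(scope="module")
def model_t_l():
    city = City("ref", 42.0, 0.67, 0.0, 300_000, (42.0, 0.0))
    config = synthetic.GeneratorConfig(cities=[city], users_per_city=0)
    dev = synthetic.seasonal_deviation_h(config, city)
    cohort = synthetic.CohortSpec(30, 40, "male", 1.0, 0.0)
    days = np.arange(1, 366, 3)
    t_l = [
        synthetic.daily_intensity(config, city, cohort, int(d),
                                  seasonal_dev_h=float(dev[d - 1]))
        .window_mean("last")
        for d in days
    ]
    return days, np.array(t_l), dev


class TestSeasonalCoupling:
    """Model-implied timing curves against the solar-midnight cue."""

    def test_activity_amplitude_compressed_relative_to_sunset(self, model_t_l):
        days, t_l, _ = model_t_l
        # Mondays only, to remove the weekday offsets from the range
        monday = (days - 1) % 7 == 0
        t_l_range = t_l[monday].max() - t_l[monday].min()
        sunsets = np.array(
            [solar.sunrise_sunset(42.0, 0.0, int(d))[1] for d in days]
        )
        sunset_range = sunsets.max() - sunsets.min()
        assert sunset_range > 2.5
        assert t_l_range < 1.0  # summer-winter swing stays under an hour

    def test_activity_curve_tracks_solar_midnight(self, model_t_l):
        days, t_l, dev = model_t_l
        monday = (days - 1) % 7 == 0
        r = np.corrcoef(t_l[monday], dev[days[monday] - 1])[0, 1]
        assert r > 0.95

    def test_amplitude_scales_with_coupling_coefficient(self, model_t_l):
        days, t_l, dev = model_t_l
        monday = (days - 1) % 7 == 0
        slope = np.polyfit(dev[days[monday] - 1], t_l[monday], 1)[0]
        assert slope == pytest.approx(0.3, abs=0.06)


class TestTlcaGapRecovery:
    def test_three_hour_age_gap_recovered_from_calls(self):
        # two cohorts whose configured low-activity periods differ by 3 h
        city = City("metro", 42.0, 0.67, 0.0, 900_000, (42.0, 0.0))
        cohorts = [
            synthetic.CohortSpec(20, 22, "male", 0.5, 0.0, 0.0),
            synthetic.CohortSpec(60, 62, "male", 0.5, 0.0, 180.0),
        ]
        config = synthetic.GeneratorConfig(
            seed=23, cities=[city], users_per_city=4000, days=(8, 63),
            cohorts=cohorts,
        )
        dataset = synthetic.generate_dataset(config)
        calls = dataset.calls.join(activity.assign_activity_days(dataset.calls["start"]))
        metrics = cohort_metrics(
            calls, dataset.subscribers,
            age_bins=[(20, 22), (60, 62)], weekdays=(1,), min_users=50,
        )
        gap = metrics.set_index("age_lo")["T_LCA"]
        assert (gap[60] - gap[20]) * 60.0 == pytest.approx(180.0, abs=10.0)
        drift = metrics.set_index("age_lo")["t_mid"]
        assert abs(drift[60] - drift[20]) * 60.0 < 5.0
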