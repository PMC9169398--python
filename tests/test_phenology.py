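import math

import numpy as np
import pytest

from phenorate.genetics import CALIMA, JAMAPA, MIDPARENT, QTLGenotype
from phenorate.phenology import (
    DailyWeatherSeries,
    closed_form_constant_day,
    predict_family,
    simulate_constant_environment,
    simulate_flowering,
)
from phenorate.rate_model import EnvironmentVector, development_rate


class TestConstantEnvironment:
    @pytest.mark.parametrize(
        "genotype, day", [(CALIMA, 34), (JAMAPA, 38)], ids=["Calima", "Jamapa"]
    )
    def test_parental_ttf_warm_short_day(self, params, warm_short_day, genotype, day):
        res = simulate_constant_environment(warm_short_day, genotype, params)
        assert res.flowered
        assert res.day_integer == day

    def test_calima_mild_short_day(self, params, mild_short_day):
        res = simulate_constant_environment(mild_short_day, CALIMA, params)
        assert res.day_integer == 38

    def test_midparent_at_centers_closed_form(self, params):
        env = EnvironmentVector(DL=12.37, Srad=18.218, Tmax=27.458, Tmin=16.128)
        res = simulate_constant_environment(env, MIDPARENT, params)
        assert res.day_interpolated == pytest.approx(1 / 0.0235198065831426, rel=1e-12)
        assert res.day_interpolated == pytest.approx(42.517, abs=5e-4)

    def test_interpolated_day_times_rate_is_one(self, params, warm_short_day):
        r = development_rate(warm_short_day, CALIMA, params)
        res = simulate_constant_environment(warm_short_day, CALIMA, params)
        assert res.day_interpolated * r == pytest.approx(1.0, rel=1e-12)

    def test_integer_day_is_ceiling_of_reciprocal_rate(self, params, rng):
        """Iterative integrator agrees with the ceiling(1/RF) closed form
        over 1000 random genotype/environment draws."""
        flowered = 0
        for _ in range(1000):
            g = QTLGenotype("rnd", tuple(rng.choice((-1, 1), size=12)))
            tmin = rng.uniform(8, 24)
            env = EnvironmentVector(
                DL=rng.uniform(10.5, 16), Srad=rng.uniform(10, 26),
                Tmax=tmin + rng.uniform(4, 12), Tmin=tmin,
            )
            res = simulate_constant_environment(env, g, params)
            cf = closed_form_constant_day(env, g, params)
            if cf is not None and cf <= 200:
                flowered += 1
                assert res.flowered
                assert res.day_integer == math.ceil(cf)
                assert res.day_interpolated == pytest.approx(cf, rel=1e-9)
            else:
                assert not res.flowered
        assert flowered > 500  # the draw box mostly yields flowering

    def test_zero_rate_never_flowers(self, params):
        # long cold days push Calima's rate negative (strong photoperiod
        # sensitivity); clamping holds P at 0
        env = EnvironmentVector(DL=18.5, Srad=18.2719, Tmax=10.0, Tmin=2.0)
        with pytest.warns(RuntimeWarning):
            res = simulate_constant_environment(env, CALIMA, params)
        assert not res.flowered
        assert res.day_integer is None and res.day_interpolated is None
        assert all(c == 0 for c in res.trajectory.cumulative)


class TestSimulateFlowering:
    def test_interpolation_brackets_integer_day(self, params, warm_short_day):
        series = DailyWeatherSeries.constant(warm_short_day, 200)
        res = simulate_flowering(series, CALIMA, params)
        assert res.day_integer - 1 < res.day_interpolated <= res.day_integer

    def test_trajectory_monotone_and_stops_past_threshold(self, params, warm_short_day):
        series = DailyWeatherSeries.constant(warm_short_day, 200)
        res = simulate_flowering(series, JAMAPA, params)
        cum = res.trajectory.cumulative
        assert all(b >= a for a, b in zip(cum, cum[1:]))
        assert cum[-1] > 1.02
        assert len(cum) < 200  # stopped early, not at horizon

    def test_series_exhausted_flagged(self, params, warm_short_day):
        short = DailyWeatherSeries.constant(warm_short_day, 10)
        res = simulate_flowering(short, CALIMA, params)
        assert not res.flowered
        assert res.series_exhausted

    def test_horizon_truncates(self, params, warm_short_day):
        series = DailyWeatherSeries.constant(warm_short_day, 200)
        res = simulate_flowering(series, CALIMA, params, horizon=20)
        assert not res.flowered
        assert not res.series_exhausted

    def test_permuting_identical_days_changes_nothing(self, params, warm_short_day, mild_short_day):
        days = [warm_short_day, mild_short_day] * 40
        a = simulate_flowering(DailyWeatherSeries("s", tuple(days)), CALIMA, params)
        # days 0 and 2 hold identical environments; swapping them is a no-op
        swapped = list(days)
        swapped[0], swapped[2] = swapped[2], swapped[0]
        b = simulate_flowering(DailyWeatherSeries("s", tuple(swapped)), CALIMA, params)
        assert a.day_integer == b.day_integer
        assert a.day_interpolated == pytest.approx(b.day_interpolated, rel=1e-12)

    def test_uniform_rate_boost_never_delays(self, params, rng):
        """Raising every day's rate (via warmer short days) cannot increase
        the interpolated flowering day."""
        tmin = 18.0
        base_days = []
        for _ in range(200):
            t = tmin + rng.uniform(0, 2)
            base_days.append(
                EnvironmentVector(DL=11.5, Srad=18.2719, Tmax=t + 8, Tmin=t)
            )
        warm_days = [
            EnvironmentVector(DL=e.DL, Srad=e.Srad, Tmax=e.Tmax + 2, Tmin=e.Tmin + 2)
            for e in base_days
        ]
        base = simulate_flowering(DailyWeatherSeries("b", tuple(base_days)), CALIMA, params)
        warm = simulate_flowering(DailyWeatherSeries("w", tuple(warm_days)), CALIMA, params)
        # Tmax+Tmin slopes are both positive for Calima, so warming raises rates
        assert warm.day_interpolated <= base.day_interpolated


class TestPredictFamily:
    def test_cardinality_and_batch_consistency(self, params, warm_short_day, mild_short_day):
        sites = {
            "warm": DailyWeatherSeries.constant(warm_short_day, 200, "warm"),
            "mild": DailyWeatherSeries.constant(mild_short_day, 200, "mild"),
        }
        table = predict_family(sites, [CALIMA, JAMAPA], params)
        assert len(table) == 4
        for _, row in table.iterrows():
            g = CALIMA if row["genotype"] == "Calima" else JAMAPA
            single = simulate_flowering(sites[row["site"]], g, params)
            assert row["day_integer"] == single.day_integer
            assert row["day_interpolated"] == pytest.approx(single.day_interpolated)

    def test_missing_site_gives_row_errors_not_failure(self, params, warm_short_day):
        # a 1-day series exhausts before flowering: flagged per-row
        sites = {"tiny": DailyWeatherSeries.constant(warm_short_day, 1, "tiny")}
        table = predict_family(sites, [CALIMA], params)
        assert len(table) == 1
        assert table.iloc[0]["flowered"] == False  # noqa: E712

    def test_factorial_family_brackets_parents(self, params, warm_short_day):
        from phenorate.genetics import enumerate_family

        fam = enumerate_family(12)
        sites = {"w": DailyWeatherSeries.constant(warm_short_day, 200, "w")}
        table = predict_family(sites, fam, params)
        assert len(table) == 4096
        days = table["day_interpolated"].to_numpy(dtype=float)
        cal = simulate_flowering(sites["w"], CALIMA, params).day_interpolated
        jam = simulate_flowering(sites["w"], JAMAPA, params).day_interpolated
        # transgressive segregation: the family range strictly contains both parents
        assert days.min() < min(cal, jam)
        assert days.max() > max(cal, jam)
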