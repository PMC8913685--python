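"""Seasonal aggregation, De Martonne aridity and delta-change scenarios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beechgrow.climate import (
    ARIDITY_BOUNDS,
    ScenarioDelta,
    aggregate_seasons,
    annual_summary,
    apply_delta,
    classify_aridity,
    de_martonne,
    ensemble_mean_delta,
    seasonal_wide,
    site_mean_ai,
)


def monthly_frame(site="A", years=(1999, 2000), tmax=10.0, tmin=0.0, prcp=50.0):
    rows = []
    for y in range(years[0], years[1] + 1):
        for m in range(1, 13):
            rows.append((site, y, m, tmax, tmin, prcp))
    return pd.DataFrame(rows, columns=["site_id", "year", "month", "tmax", "tmin", "prcp"])


class TestSeasons:
    def test_winter_mean_spans_december_of_prior_year(self):
        m = monthly_frame()
        m.loc[(m.year == 1999) & (m.month == 12), "tmax"] = 1.0
        m.loc[(m.year == 2000) & (m.month == 1), "tmax"] = 2.0
        m.loc[(m.year == 2000) & (m.month == 2), "tmax"] = 3.0
        s = aggregate_seasons(m)
        win = s[(s.year == 2000) & (s.season == "WIN")]
        assert win["tmax_mean"].iloc[0] == pytest.approx(2.0)

    def test_summer_precipitation_is_summed(self):
        m = monthly_frame()
        m.loc[(m.year == 2000) & m.month.isin([6, 7, 8]), "prcp"] = [10.0, 20.0, 30.0]
        s = aggregate_seasons(m)
        assert s[(s.year == 2000) & (s.season == "SUM")]["pp_sum"].iloc[0] == pytest.approx(60.0)

    def test_missing_prior_december_omits_winter_only(self):
        m = monthly_frame(years=(1999, 2000))
        m = m[~((m.year == 1999) & (m.month == 12))]
        s = aggregate_seasons(m)
        emitted = set(s[s.year == 2000]["season"].astype(str))
        assert emitted == {"pSUM", "pAUT", "SPR", "SUM", "AUT"}

    def test_six_seasons_for_complete_years(self):
        s = aggregate_seasons(monthly_frame(years=(1998, 2000)))
        counts = s[s.year.isin([1999, 2000])].groupby("year", observed=True).size()
        assert (counts == 6).all()
        wide = seasonal_wide(s)
        assert wide.shape[1] == 2 + 18  # ids + 3 variables x 6 seasons

    def test_tmin_above_tmax_rejected(self):
        m = monthly_frame(tmax=1.0, tmin=5.0)
        with pytest.raises(ValueError, match="tmin"):
            aggregate_seasons(m)


class TestDeMartonne:
    @pytest.mark.parametrize(
        "p,t,expect",
        [(500.0, 10.0, 25.0), (0.0, 5.0, 0.0), (1200.0, 8.6, 1200.0 / 18.6)],
    )
    def test_index_values(self, p, t, expect):
        assert de_martonne(p, t) == pytest.approx(expect)

    def test_pole_rejected(self):
        with pytest.raises(ValueError, match="-10"):
            de_martonne(500.0, -10.0)

    def test_humid_example_classifies_extremely_humid(self):
        assert classify_aridity(de_martonne(1200.0, 8.6)) == "extremely humid"

    @pytest.mark.parametrize(
        "ai,cls",
        [
            (0.0, "arid"),
            (15.0, "semi-arid"),
            (10.0, "semi-arid"),
            (20.0, "Mediterranean"),
            (24.0, "semi-humid"),
            (28.0, "humid"),
            (35.0, "very humid"),
            (55.0, "extremely humid"),
        ],
    )
    def test_class_boundaries_are_lower_inclusive(self, ai, cls):
        assert classify_aridity(ai) == cls

    def test_negative_index_rejected(self):
        with pytest.raises(ValueError):
            classify_aridity(-0.1)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(ai=st.floats(0.0, 200.0))
    def test_classification_total_and_consistent_with_bounds(self, ai):
        cls = classify_aridity(ai)
        idx = sum(ai >= b for b in ARIDITY_BOUNDS)
        from beechgrow.climate import ARIDITY_CLASSES

        assert cls == ARIDITY_CLASSES[idx]

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        p=st.floats(1.0, 3000.0),
        t=st.floats(-9.0, 30.0),
        dp=st.floats(0.1, 100.0),
        dt=st.floats(0.1, 5.0),
    )
    def test_monotone_in_p_and_t(self, p, t, dp, dt):
        assert de_martonne(p + dp, t) > de_martonne(p, t)
        assert de_martonne(p, t + dt) < de_martonne(p, t)


class TestSiteAi:
    def test_constant_climate_gives_exact_index(self):
        # P=600 mm/yr, T=10 C -> AI = 600/20 = 30 in every year
        m = monthly_frame(years=(1950, 1960), tmax=10.0, tmin=10.0, prcp=50.0)
        ai = site_mean_ai(m, window=(1950, 1960))
        assert ai["A"] == pytest.approx(30.0)

    def test_mean_of_annual_indices(self, small_network):
        """Matches a brute-force year loop over annual AI values."""
        monthly = small_network.climate
        got = site_mean_ai(monthly, window=(1980, 2000))
        ann = annual_summary(monthly)
        ann = ann[(ann.year >= 1980) & (ann.year <= 2000)]
        for site in got.index[:4]:
            sub = ann[ann.site_id == site]
            brute = np.mean([de_martonne(p, t) for p, t in zip(sub.p_annual, sub.t_annual)])
            assert got[site] == pytest.approx(brute, rel=1e-12)

    def test_empty_window_rejected(self, small_network):
        with pytest.raises(ValueError):
            site_mean_ai(small_network.climate, window=(2010, 2000))


def delta_table(sites, value_t=0.0, value_p=0.0):
    from beechgrow.climate import SEASONS

    idx = pd.MultiIndex.from_product([sites, SEASONS], names=["site_id", "season"])
    return pd.DataFrame(
        {
            "site_id": idx.get_level_values(0),
            "season": idx.get_level_values(1),
            "dtmax": value_t,
            "dtmin": value_t,
            "dpp": value_p,
        }
    )


class TestDeltas:
    def test_two_member_mean(self):
        t1 = ScenarioDelta("S", (2020, 2050), delta_table(["A"], value_t=1.0))
        t2 = ScenarioDelta("S", (2020, 2050), delta_table(["A"], value_t=3.0))
        p1 = ScenarioDelta("S", (2020, 2050), delta_table(["A"], value_p=4.0))
        mean = ensemble_mean_delta([t1, t2], [p1])
        assert (mean.table["dtmax"] == 2.0).all()
        assert (mean.table["dpp"] == 4.0).all()

    def test_single_member_is_identity(self):
        t1 = ScenarioDelta("S", (2020, 2050), delta_table(["A", "B"], value_t=1.5))
        mean = ensemble_mean_delta([t1], [t1])
        assert (mean.table["dtmax"] == 1.5).all()

    def test_mismatched_locations_rejected(self):
        t1 = ScenarioDelta("S", (2020, 2050), delta_table(["A"]))
        t2 = ScenarioDelta("S", (2020, 2050), delta_table(["B"]))
        with pytest.raises(ValueError, match="mismatched"):
            ensemble_mean_delta([t1, t2], [t1])

    def test_generator_ensemble_matches_loop_mean(self, small_network):
        """Ensemble mean equals an explicit per-cell loop over members."""
        from beechgrow.synthetic import generate_scenario_ensemble

        members = generate_scenario_ensemble(
            small_network.sites[:4], n_temp_models=21, n_precip_models=26, seed=9
        )
        (temps, precips) = members[("SSP1-2.6", (2020, 2050))]
        assert len(temps) == 21 and len(precips) == 26
        mean = ensemble_mean_delta(temps, precips)
        key = mean.table.set_index(["site_id", "season"])
        row = key.index[3]
        loop = np.mean([m.table.set_index(["site_id", "season"]).loc[row, "dtmax"] for m in temps])
        assert key.loc[row, "dtmax"] == pytest.approx(loop, rel=1e-12)

    def test_apply_zero_delta_is_identity(self, small_seasonal):
        zero = ScenarioDelta(
            "S", (2020, 2050), delta_table(sorted(small_seasonal.site_id.unique()))
        )
        out = apply_delta(small_seasonal, zero)
        pd.testing.assert_frame_equal(out, small_seasonal)

    def test_precipitation_floored_at_zero(self, small_seasonal):
        big = delta_table(sorted(small_seasonal.site_id.unique()), value_p=-1e9)
        out = apply_delta(small_seasonal, ScenarioDelta("S", (2020, 2050), big))
        assert (out["pp_sum"] == 0.0).all()

    def test_uniform_warming_shifts_every_season(self, small_seasonal):
        d = delta_table(sorted(small_seasonal.site_id.unique()), value_t=2.0)
        out = apply_delta(small_seasonal, ScenarioDelta("S", (2020, 2050), d))
        np.testing.assert_allclose(out["tmax_mean"], small_seasonal["tmax_mean"] + 2.0)
        np.testing.assert_allclose(out["tmin_mean"], small_seasonal["tmin_mean"] + 2.0)

    def test_uncovered_baseline_rejected(self, small_seasonal):
        d = delta_table(["NOT_A_SITE"])
        with pytest.raises(ValueError, match="cover"):
            apply_delta(small_seasonal, ScenarioDelta("S", (2020, 2050), d))
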