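"""Tests for the nested-plot drought analysis pipeline."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from growthdom import drought_pipeline as dp
from growthdom import synthetic_stands as ss
from growthdom.errors import UnmappedIntervalError, ValidationError
from growthdom.partition_indices import basal_area
from growthdom.types import DEFAULT_PERIODS


@pytest.fixture(scope="module")
def drought_census():
    base = ss.StandConfig(structure="even_aged", n_trees=25, sigma=0.05, seed=2)
    return ss.generate_plot_network(30, ss.default_scenario(), base, seed=2)


@pytest.fixture(scope="module")
def intervals(drought_census):
    return dp.build_interval_table(drought_census)


class TestExpansionWeight:
    def test_inner_circle(self):
        assert dp.expansion_weight(15.0) == 50.0  # 10000 / 200

    def test_outer_circle(self):
        assert dp.expansion_weight(40.0) == 20.0  # 10000 / 500

    def test_boundary_belongs_to_outer(self):
        assert dp.expansion_weight(36.0) == 20.0

    def test_below_threshold_rejected(self):
        with pytest.raises(ValidationError, match="threshold"):
            dp.expansion_weight(11.9)

    def test_vectorized(self):
        np.testing.assert_array_equal(
            dp.expansion_weight(np.array([12.0, 35.9, 36.0, 80.0])),
            [50.0, 50.0, 20.0, 20.0],
        )


class TestAnnualize:
    def test_multi_year(self):
        assert dp.annualize(0.006, 3.0) == pytest.approx(0.002)

    def test_single_year_pass_through(self):
        assert dp.annualize(0.002, 1.0) == pytest.approx(0.002)

    def test_zero_interval_rejected(self):
        with pytest.raises(ValidationError):
            dp.annualize(0.002, 0.0)


class TestAssignPeriod:
    def test_spring_to_spring_decade(self):
        label, years = dp.assign_period(dt.date(2010, 4, 1), dt.date(2018, 4, 15))
        assert label == "2010-2017"
        assert years == 8

    def test_spring_to_autumn_drought_year(self):
        label, years = dp.assign_period(dt.date(2018, 4, 15), dt.date(2018, 9, 10))
        assert label == "2018"
        assert years == 1

    def test_autumn_to_autumn(self):
        label, years = dp.assign_period(dt.date(2019, 9, 15), dt.date(2020, 9, 15))
        assert label == "2020"
        assert years == 1

    def test_unmapped_interval(self):
        with pytest.raises(UnmappedIntervalError):
            dp.assign_period(dt.date(1950, 4, 1), dt.date(1960, 4, 1))

    def test_straddling_interval_rejected(self):
        with pytest.raises(UnmappedIntervalError):
            dp.assign_period(dt.date(2016, 4, 1), dt.date(2019, 9, 1))

    def test_unordered_dates(self):
        with pytest.raises(ValidationError):
            dp.assign_period(dt.date(2018, 4, 1), dt.date(2018, 4, 1))

    def test_periods_partition_timeline(self):
        # every single-season interval inside the configured span maps to
        # exactly one period label
        for year in range(1984, 2021):
            label, years = dp.assign_period(
                dt.date(year, 9, 15), dt.date(year + 1, 9, 15),
            ) if year < 2020 else (None, None)
            if label is None:
                continue
            assert years == 1
            matches = [p for p in DEFAULT_PERIODS
                       if p.start_year <= year + 1 <= p.end_year]
            assert [m.label for m in matches] == [label]


class TestClassifyStandType:
    def _plot(self, beech_dbh, other_dbh):
        rows = [("beech", d) for d in beech_dbh] + [("other", d) for d in other_dbh]
        return pd.DataFrame(
            {
                "tree_id": [f"t{i}" for i in range(len(rows))],
                "dbh_cm": [d for _, d in rows],
                "species": [s for s, _ in rows],
                "status": "live",
                "weight": 1.0,
            }
        )

    def test_dominated(self):
        assert dp.classify_stand_type(self._plot([40, 40, 40], [20])) == "beech_dominated"

    def test_admixed(self):
        assert dp.classify_stand_type(self._plot([20], [40, 40, 40])) == "beech_admixed"

    def test_exactly_half_is_dominated(self):
        assert dp.classify_stand_type(self._plot([30], [30])) == "beech_dominated"

    def test_no_live_trees(self):
        empty = self._plot([], []).assign(status="dead")
        with pytest.raises(ValidationError):
            dp.classify_stand_type(empty)


class TestFilterPlots:
    def test_threshold(self):
        plots = {
            "keep": pd.DataFrame({"status": ["live"] * 8}),
            "drop": pd.DataFrame({"status": ["live"] * 7}),
        }
        kept, log = dp.filter_plots(plots, min_trees=8)
        assert set(kept) == {"keep"}
        assert log.set_index("plot_id").loc["drop", "retained"] == False  # noqa: E712

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            kept, log = dp.filter_plots({})
        assert kept == {} and log.empty


class TestIntervalTable:
    def test_columns_and_periods(self, intervals):
        assert set(intervals["period"]) == {p.label for p in DEFAULT_PERIODS}
        assert (intervals["bai_annual"] >= 0).all()
        assert set(intervals["weight"].unique()) <= {20.0, 50.0}

    def test_stand_ba_conservation(self, intervals):
        # stand basal area equals the sum of weight x tree basal area
        recomputed = (
            (intervals["weight"] * basal_area(intervals["dbh_prev"].to_numpy()))
            .groupby([intervals["plot_id"], intervals["period"]])
            .transform("sum")
        )
        np.testing.assert_allclose(intervals["stand_ba"], recomputed, rtol=1e-12)

    def test_annualization_against_census(self, drought_census):
        iv = dp.build_interval_table(drought_census)
        decade = iv[iv["period"] == "1995-2004"]
        assert (decade["interval_years"] == 10).all()

    def test_unweighted_mode(self, drought_census):
        iv = dp.build_interval_table(drought_census, weighted=False)
        assert (iv["weight"] == 1.0).all()

    def test_needs_two_censuses(self):
        single = pd.DataFrame(
            {
                "plot_id": "p1",
                "tree_id": ["a", "b"],
                "census_date": "2018-04-15",
                "dbh_cm": [20.0, 30.0],
                "species": "beech",
                "status": "live",
            }
        )
        with pytest.raises(ValidationError, match="interval"):
            dp.build_interval_table(single)


class TestDcPeriodModel:
    def test_reference_coding_invariance(self, intervals):
        dc = dp.dc_by_period(intervals)
        f1 = dp._fit_mixedlm(
            "dc ~ C(period, Treatment('2018')) * C(stand_type)", dc, groups="plot_id"
        )
        f2 = dp._fit_mixedlm(
            "dc ~ C(period, Treatment('1984-1994')) * C(stand_type)", dc, groups="plot_id"
        )
        diff = np.abs(np.asarray(f1.fittedvalues) - np.asarray(f2.fittedvalues))
        assert diff.max() < 1e-8

    def test_single_period_rejected(self, intervals):
        dc = dp.dc_by_period(intervals)
        with pytest.raises(ValidationError, match=">= 2"):
            dp.fit_dc_period_model(dc[dc["period"] == "2018"])

    def test_letters_consistent_with_pvalues(self, intervals):
        dc = dp.dc_by_period(intervals)
        eff = dp.fit_dc_period_model(dc)
        for stype in eff.means["stand_type"].unique():
            cells = eff.means[eff.means["stand_type"] == stype]
            letters = dict(zip(cells["period"], cells["letters"]))
            pw = eff.pairwise[eff.pairwise["stand_type"] == stype]
            for row in pw.itertuples(index=False):
                shared = set(letters[row.period_a]) & set(letters[row.period_b])
                if row.p_adj <= 0.05:
                    assert not shared, (row.period_a, row.period_b)
                else:
                    assert shared, (row.period_a, row.period_b)

    def test_recovers_post_drought_dc_drop(self, intervals):
        dc = dp.dc_by_period(intervals)
        eff = dp.fit_dc_period_model(dc)
        dom = eff.means[eff.means["stand_type"] == "beech_dominated"].set_index("period")
        assert dom.loc["2019", "estimate"] < dom.loc["2018", "estimate"]
        assert dom.loc["2020", "estimate"] < dom.loc["2018", "estimate"]
        pw = eff.pairwise[
            (eff.pairwise["stand_type"] == "beech_dominated")
            & (eff.pairwise["period_a"] == "2018")
            & (eff.pairwise["period_b"].isin(["2019", "2020"]))
        ]
        assert (pw["p_adj"] < 0.05).all()

    def test_null_scenario_no_drought_signal(self):
        base = ss.StandConfig(structure="even_aged", n_trees=25, sigma=0.05, seed=31)
        census = ss.generate_plot_network(30, ss.null_scenario(), base, seed=31)
        dc = dp.dc_by_period(dp.build_interval_table(census))
        eff = dp.fit_dc_period_model(dc)
        pw = eff.pairwise[
            (eff.pairwise["stand_type"] == "beech_dominated")
            & (eff.pairwise["period_a"] == "2018")
        ]
        assert (pw["p_adj"] > 0.05).all()


class TestBaiPeriodModel:
    def test_drought_drops_bai_below_preceding_period(self, intervals):
        # size drift raises absolute BAI over the 36-year series, so the
        # drought signal is a drop relative to the preceding period
        eff = dp.fit_bai_period_model(intervals)
        dom = eff.means[eff.means["stand_type"] == "beech_dominated"].set_index("period")
        assert dom.loc["2018", "estimate"] < dom.loc["2010-2017", "estimate"]
        assert dom.loc["2019", "estimate"] < dom.loc["2010-2017", "estimate"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            dp.fit_bai_period_model(pd.DataFrame(columns=["bai_annual", "period", "stand_type"]))


class TestCompactLetters:
    def test_all_different(self):
        pw = pd.DataFrame(
            [
                {"period_a": "a1", "period_b": "a2", "p_adj": 0.001},
                {"period_a": "a1", "period_b": "a3", "p_adj": 0.001},
                {"period_a": "a2", "period_b": "a3", "p_adj": 0.001},
            ]
        )
        letters = dp.compact_letters(["a1", "a2", "a3"], [1.0, 2.0, 3.0], pw)
        assert len({letters["a1"], letters["a2"], letters["a3"]}) == 3

    def test_all_same(self):
        pw = pd.DataFrame(
            [
                {"period_a": "a1", "period_b": "a2", "p_adj": 0.9},
                {"period_a": "a1", "period_b": "a3", "p_adj": 0.9},
                {"period_a": "a2", "period_b": "a3", "p_adj": 0.9},
            ]
        )
        letters = dp.compact_letters(["a1", "a2", "a3"], [1.0, 2.0, 3.0], pw)
        assert letters["a1"] == letters["a2"] == letters["a3"]

    def test_chain_overlap(self):
        # a1 != a3, both similar to a2: a2 shares a letter with each
        pw = pd.DataFrame(
            [
                {"period_a": "a1", "period_b": "a2", "p_adj": 0.5},
                {"period_a": "a1", "period_b": "a3", "p_adj": 0.001},
                {"period_a": "a2", "period_b": "a3", "p_adj": 0.5},
            ]
        )
        letters = dp.compact_letters(["a1", "a2", "a3"], [1.0, 2.0, 3.0], pw)
        assert set(letters["a1"]) & set(letters["a2"])
        assert set(letters["a2"]) & set(letters["a3"])
        assert not set(letters["a1"]) & set(letters["a3"])


class TestSizeDensitySlopes:
    def test_recovers_linear_size_effect(self, intervals):
        slopes = dp.size_and_density_slopes(intervals)
        pre = slopes[
            (slopes["period"] == "1995-2004") & (slopes["stand_type"] == "beech_dominated")
        ].iloc[0]
        assert pre["size_slope"] > 0
        assert pre["size_slope"] / pre["size_se"] > 2
        assert 0 <= pre["r2_size"] <= 1

    def test_drought_reduces_size_slope(self, intervals):
        slopes = dp.size_and_density_slopes(intervals)
        dom = slopes[slopes["stand_type"] == "beech_dominated"].set_index(
            slopes.loc[slopes["stand_type"] == "beech_dominated", "period"]
        )
        assert dom.loc["2019", "size_slope"] < dom.loc["2010-2017", "size_slope"]

    def test_small_cells_flagged(self, intervals):
        tiny = intervals.head(5)
        slopes = dp.size_and_density_slopes(tiny)
        assert (slopes["flags"] == "too_few_trees").all()
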