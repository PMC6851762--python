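"""Deterministic preparation operators: aggregation, rolling sums,
interpolation, filtering, panel assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fire_extremes.preprocess import (
    aggregate_daily_to_monthly,
    assemble_panel,
    filter_events,
    interpolate_housing,
    rolling_prior_12_sum,
)


def _daily(region, year, month, values):
    return pd.DataFrame(
        {
            "region": region,
            "year": year,
            "month": month,
            "day": np.arange(1, len(values) + 1),
            "temperature": values,
        }
    )


class TestAggregateDaily:
    def test_constant_month(self):
        out = aggregate_daily_to_monthly(_daily(1, 2000, 1, [2.0] * 30))
        assert out.loc[0, "temperature"] == 2.0

    def test_arithmetic_mean(self):
        out = aggregate_daily_to_monthly(_daily(1, 2000, 1, [1.0, 2.0, 3.0]))
        assert out.loc[0, "temperature"] == 2.0

    def test_regions_independent(self):
        daily = pd.concat(
            [_daily(1, 2000, 1, [10.0, 20.0]), _daily(2, 2000, 1, [100.0, 200.0])]
        )
        out = aggregate_daily_to_monthly(daily).set_index("region")
        assert out.loc[1, "temperature"] == 15.0
        assert out.loc[2, "temperature"] == 150.0

    def test_empty_cell_raises_with_name(self):
        daily = pd.concat(
            [
                _daily(1, 2000, 1, [1.0]),
                _daily(1, 2000, 2, [1.0]),
                _daily(2, 2000, 1, [1.0]),
            ]
        )
        with pytest.raises(ValueError, match="region 2"):
            aggregate_daily_to_monthly(daily)


class TestRollingPrior12:
    def _series(self, values):
        return pd.DataFrame(
            {"region": 1, "t": np.arange(1, len(values) + 1), "precipitation": values}
        )

    def test_constant_series(self):
        out = rolling_prior_12_sum(self._series([1.0] * 30))
        assert np.allclose(out["precip_12mo"].to_numpy()[12:], 12.0)

    def test_ramp(self):
        out = rolling_prior_12_sum(self._series(np.arange(1.0, 25.0)))
        # at t = 13 the prior year is 1 + ... + 12
        assert out.loc[out["t"] == 13, "precip_12mo"].iloc[0] == 78.0

    def test_first_year_unavailable(self):
        out = rolling_prior_12_sum(self._series([1.0] * 20))
        assert out["precip_12mo"].to_numpy()[:12].tolist() == [np.nan] * 0 or np.all(
            np.isnan(out["precip_12mo"].to_numpy()[:12])
        )
        assert np.all(np.isfinite(out["precip_12mo"].to_numpy()[12:]))

    def test_excludes_current_month(self):
        values = np.zeros(25)
        values[12] = 5.0  # a spike at t = 13
        out = rolling_prior_12_sum(self._series(values)).set_index("t")["precip_12mo"]
        assert out.loc[13] == 0.0  # current month not included
        assert out.loc[14] == 5.0

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            rolling_prior_12_sum(self._series([1.0] * 12))


class TestInterpolateHousing:
    anchors = pd.DataFrame(
        {"region": [1, 1], "year": [2000, 2010], "housing_density": [10.0, 20.0]}
    )

    def test_midpoint(self):
        out = interpolate_housing(
            self.anchors, years=np.array([2005]), months=np.array([6])
        )
        t = 2005 + 5.5 / 12
        assert np.isclose(out["housing_density"].iloc[0], 10 + (t - 2000))

    def test_constant_anchors(self):
        flat = self.anchors.assign(housing_density=[7.0, 7.0])
        out = interpolate_housing(
            flat, years=np.array([1995, 2005, 2016]), months=np.array([1, 6, 12])
        )
        assert np.allclose(out["housing_density"], 7.0)

    def test_linear_extension_beyond_last_anchor(self):
        # evaluated at continuous time 2016.0 exactly: month midpoint for
        # December 2015 + half a month is awkward, so check via slope
        out = interpolate_housing(
            self.anchors, years=np.array([2016]), months=np.array([1])
        )
        t = 2016 + 0.5 / 12
        assert np.isclose(out["housing_density"].iloc[0], 10 + (t - 2000))

    def test_single_anchor_raises(self):
        single = self.anchors.iloc[:1]
        with pytest.raises(ValueError):
            interpolate_housing(single, years=np.array([2005]), months=np.array([1]))


class TestFilterEvents:
    def test_threshold_and_exceedance(self):
        raw = pd.DataFrame(
            {
                "year": 2000,
                "month": 1,
                "region": 1,
                "size_ha": [1000.0, 300.0, 500.0],
            }
        )
        out = filter_events(raw, threshold_ha=405.0)
        assert out["size_ha"].tolist() == [1000.0, 500.0]
        assert out["exceedance_ha"].tolist() == [595.0, 95.0]

    def test_all_below_threshold_is_valid_empty(self):
        raw = pd.DataFrame({"year": 2000, "month": 1, "region": 1, "size_ha": [10.0]})
        assert len(filter_events(raw)) == 0

    def test_exact_threshold_removed(self):
        raw = pd.DataFrame({"year": 2000, "month": 1, "region": 1, "size_ha": [405.0]})
        assert len(filter_events(raw)) == 0

    def test_nonpositive_sizes_raise(self):
        raw = pd.DataFrame({"year": 2000, "month": 1, "region": 1, "size_ha": [-1.0]})
        with pytest.raises(ValueError):
            filter_events(raw)


class TestAssemblePanel:
    def test_grid_complete_and_split_counts(self, toy_panel, toy_hierarchy):
        s = toy_hierarchy.n_l3
        t_usable = toy_panel["t"].nunique()
        assert len(toy_panel) == s * t_usable
        n_train_months = (toy_panel[toy_panel.split == "train"]["t"]).nunique()
        assert (toy_panel["split"] == "train").sum() == n_train_months * s
        # split is a time cut
        by_t = toy_panel.groupby("t")["split"].nunique()
        assert (by_t == 1).all()

    def test_counts_conserved(self, toy_panel, toy_catalog):
        assert toy_panel["count"].sum() == len(toy_catalog)
        assert (toy_panel["count"] >= 0).all()

    def test_first_year_dropped(self, toy_panel):
        assert toy_panel["t"].min() == 13

    def test_unknown_region_event_raises(self, toy_covariates, toy_hierarchy):
        bad = pd.DataFrame(
            {
                "event_id": [1],
                "year": [2001],
                "month": [2],
                "region": [999],
                "size_ha": [800.0],
                "exceedance_ha": [395.0],
            }
        )
        with pytest.raises(ValueError, match="event_ids"):
            assemble_panel(bad, toy_covariates, toy_hierarchy, split_month=108)

    def test_idempotent_on_own_output(self, toy_panel, toy_catalog, toy_hierarchy):
        again = assemble_panel(toy_catalog, toy_panel, toy_hierarchy, split_month=108)
        pd.testing.assert_frame_equal(
            again.sort_values(["t", "region"]).reset_index(drop=True), toy_panel
        )


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.lists(st.floats(405.1, 1e6), min_size=0, max_size=30))
def test_filter_conserves_and_shifts(sizes):
    raw = pd.DataFrame({"year": 2000, "month": 1, "region": 1, "size_ha": sizes})
    out = filter_events(raw)
    assert len(out) == len(sizes)
    assert np.all(out["exceedance_ha"] > 0)
    assert np.allclose(out["size_ha"] - out["exceedance_ha"], 405.0)
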