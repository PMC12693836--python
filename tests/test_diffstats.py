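from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from conftest import make_dataset
from winotherm.diffstats import (
    difference_series,
    monthly_aggregate,
    per_day_phase_means,
    phase_boxplot_stats,
)
from winotherm.errors import ChannelError, ConfigurationError


class TestDifferenceSeries:
    def test_constant_channels_give_constant_difference(self, constant_dataset):
        s = difference_series(constant_dataset, "dT_TB_int_living")
        assert np.allclose(s.samples, 0.5)
        assert s.minuend == "living_top"

    def test_identical_channels_give_zero(self):
        ds = make_dataset({"living_top": 25.0, "living_bottom": 25.0}, days=1.0)
        s = difference_series(ds, "dT_TB_int_living")
        assert np.allclose(s.samples, 0.0)

    def test_antisymmetry_of_top_and_bottom_roles(self, constant_dataset):
        top = difference_series(constant_dataset, "dT_top")  # living_top - control_top
        # swap roles by negation: there is no reverse kind, so check against raw channels
        expected = (
            constant_dataset.frame["control_top"] - constant_dataset.frame["living_top"]
        )
        assert np.allclose(-top.samples, expected)

    def test_missing_channel_named_in_error(self):
        ds = make_dataset({"living_top": 25.0}, days=1.0)
        with pytest.raises(ChannelError, match="living_bottom"):
            difference_series(ds, "dT_TB_int_living")

    def test_unknown_kind_rejected(self, constant_dataset):
        with pytest.raises(ConfigurationError):
            difference_series(constant_dataset, "dT_sideways")

    def test_offset_on_both_channels_cancels(self, constant_dataset):
        shifted = constant_dataset.frame.copy()
        shifted[["living_top", "living_bottom"]] += 1.7
        ds2 = type(constant_dataset)(frame=shifted, sampling_period=60.0)
        s1 = difference_series(constant_dataset, "dT_TB_int_living")
        s2 = difference_series(ds2, "dT_TB_int_living")
        assert np.allclose(s1.samples, s2.samples)

    def test_offset_on_minuend_shifts_exactly(self, constant_dataset):
        shifted = constant_dataset.frame.copy()
        shifted["living_top"] += 0.3
        ds2 = type(constant_dataset)(frame=shifted, sampling_period=60.0)
        s1 = difference_series(constant_dataset, "dT_TB_int_living")
        s2 = difference_series(ds2, "dT_TB_int_living")
        assert np.allclose(s2.samples - s1.samples, 0.3)

    def test_four_channel_algebraic_identity(self, default_sim):
        """dT_top − dT_bott == dT_TB_int_living − dT_TB_int_control pointwise."""
        ds = default_sim.dataset
        lhs = (
            difference_series(ds, "dT_top").samples
            - difference_series(ds, "dT_bott").samples
        )
        rhs = (
            difference_series(ds, "dT_TB_int_living").samples
            - difference_series(ds, "dT_TB_int_control").samples
        )
        assert np.allclose(lhs, rhs)


class TestAggregates:
    def _series_with_daily_values(self, values):
        n_days = len(values)
        ds = make_dataset({"living_top": 25.0, "control_top": 25.0}, days=n_days)
        frame = ds.frame.copy()
        for i, v in enumerate(values):
            day_mask = frame.index.date == frame.index.date[0] + pd.Timedelta(days=i).to_pytimedelta()
            frame.loc[day_mask, "living_top"] = 25.0 + v
        ds2 = type(ds)(frame=frame, sampling_period=60.0)
        return difference_series(ds2, "dT_top")

    def test_boxplot_stats_over_daily_means(self):
        s = self._series_with_daily_values([0.5, 0.55, 0.6])
        stats = phase_boxplot_stats(s, phase="D1")
        assert stats["median"] == pytest.approx(0.55)
        assert stats["mean"] == pytest.approx(0.55)
        assert stats["n_days"] == 3

    def test_single_day_collapses_five_numbers(self):
        s = self._series_with_daily_values([0.42])
        stats = phase_boxplot_stats(s, phase="D2")
        for key in ("min", "q1", "median", "q3", "max", "mean"):
            assert stats[key] == pytest.approx(0.42)
        assert stats["sd"] == 0.0

    def test_constant_series_has_zero_sd(self):
        s = self._series_with_daily_values([0.3, 0.3, 0.3])
        assert phase_boxplot_stats(s, phase="N1")["sd"] == pytest.approx(0.0)

    def test_monthly_mean_over_daily_means(self):
        s = self._series_with_daily_values([0.0, 2.0])
        daily = per_day_phase_means(s)
        monthly = monthly_aggregate(daily, "D1")
        assert len(monthly) == 1
        assert monthly["mean"].iloc[0] == pytest.approx(1.0)
        assert monthly["valid_days"].iloc[0] == 2

    def test_single_valid_day_month(self):
        s = self._series_with_daily_values([0.7])
        monthly = monthly_aggregate(per_day_phase_means(s), "N2")
        assert monthly["mean"].iloc[0] == pytest.approx(0.7)
        assert monthly["sd"].iloc[0] == 0.0
        assert monthly["valid_days"].iloc[0] == 1

    def test_interrupted_day_drops_from_monthly(self):
        s = self._series_with_daily_values([0.0, 2.0, 4.0])
        # wipe most of day 2's D1 window so it fails the coverage rule
        keep = ~(
            (s.samples.index >= datetime(2022, 4, 2, 8, 0))
            & (s.samples.index < datetime(2022, 4, 2, 15, 0))
        )
        s.samples = s.samples[keep]
        daily = per_day_phase_means(s, min_coverage=0.9)
        monthly = monthly_aggregate(daily, "D1")
        assert monthly["valid_days"].iloc[0] == 2
        assert monthly["mean"].iloc[0] == pytest.approx((0.0 + 4.0) / 2)
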