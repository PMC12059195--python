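"""Baselines, reserves, strain components and the PSI."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from heatwear.core import Device, EpochGrid, ParticipantProfile
from heatwear.strain import (InsufficientDataError, ReserveCapacities,
                             StrainParameters, daily_strain_summary,
                             diurnal_profile, reserve_capacities,
                             resting_baselines, strain_series, tanaka_max_hr)

from conftest import make_series


def series_of(device, values, freq="60s", start="2023-02-06 08:00"):
    ts = pd.date_range(start, periods=len(values), freq=freq)
    return make_series(device, ts, value=list(map(float, values)))


class TestTanaka:
    @pytest.mark.parametrize("age,expected", [(30, 187.0), (20, 194.0), (45, 176.5)])
    def test_age_predicted_peak(self, age, expected):
        assert tanaka_max_hr(age) == pytest.approx(expected)

    @pytest.mark.parametrize("age", [0, -3, 130])
    def test_out_of_range_age(self, age):
        with pytest.raises(ValueError):
            tanaka_max_hr(age)


class TestBaselines:
    def test_constant_series(self):
        hr = series_of(Device.HR, [60] * 10)
        cbt = series_of(Device.CBT, [36.5] * 10)
        rhr, t0 = resting_baselines(hr, cbt)
        assert (rhr, t0) == (60.0, 36.5)

    def test_minimum_of_epoch_means(self):
        # three 5-min epochs of constant 55, 48, 90
        hr = series_of(Device.HR, [55] * 5 + [48] * 5 + [90] * 5)
        cbt = series_of(Device.CBT, [36.2] * 15)
        rhr, _ = resting_baselines(hr, cbt, EpochGrid(5))
        assert rhr == 48.0

    def test_empty_series_is_insufficient(self):
        hr = series_of(Device.HR, [])
        cbt = series_of(Device.CBT, [36.5])
        with pytest.raises(InsufficientDataError):
            resting_baselines(hr, cbt)

    @given(st.lists(st.floats(min_value=40, max_value=200, allow_nan=False),
                    min_size=1, max_size=120))
    def test_epoch_min_never_below_raw_min(self, values):
        hr = series_of(Device.HR, values)
        cbt = series_of(Device.CBT, [36.5] * len(values))
        rhr, _ = resting_baselines(hr, cbt, EpochGrid(5))
        assert rhr >= min(values) - 1e-12


class TestReserves:
    def profile(self, age=30):
        return ParticipantProfile("P", "female", age, 160.0, 55.0, 21.5, "H01")

    @pytest.mark.parametrize("resting_cbt,expected", [(36.11, 3.39), (36.07, 3.43)])
    def test_cbt_reserve_from_critical_temperature(self, resting_cbt, expected):
        res = reserve_capacities(self.profile(), 50.0, resting_cbt)
        assert res.cbt_reserve == pytest.approx(expected)

    def test_hrr_from_predicted_peak(self):
        # Methods definition: HRR = Tanaka(age) - RHR
        assert tanaka_max_hr(26.1) - 51.66 == pytest.approx(138.07)

    def test_reserve_plus_resting_equals_critical(self):
        res = reserve_capacities(self.profile(), 55.0, 36.3)
        assert res.cbt_reserve + res.resting_cbt == 39.5

    def test_degenerate_participant_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            reserve_capacities(self.profile(), 50.0, 39.6)
        with pytest.raises(ValueError, match="degenerate"):
            reserve_capacities(self.profile(), 190.0, 36.2)


def reserves(rhr=50.0, peak=190.0, t0=36.0):
    return ReserveCapacities(rhr, peak, t0, 39.5)


class TestStrainSeries:
    def test_rest_state_is_zero_strain(self):
        hr = series_of(Device.HR, [50] * 5)
        cbt = series_of(Device.CBT, [36.0] * 5)
        df = strain_series(hr, cbt, reserves())
        assert (df["cardiac"] == 0).all()
        assert (df["thermal"] == 0).all()
        assert (df["psi"] == 0).all()

    def test_midpoint_gives_psi_five(self):
        hr = series_of(Device.HR, [120] * 5)       # halfway through HRR 140
        cbt = series_of(Device.CBT, [37.75] * 5)   # halfway through reserve 3.5
        df = strain_series(hr, cbt, reserves())
        assert df["cardiac"].iloc[0] == pytest.approx(50.0)
        assert df["thermal"].iloc[0] == pytest.approx(50.0)
        assert df["psi"].iloc[0] == pytest.approx(5.0)

    def test_psi_of_mean_components_is_weighted_sum(self):
        # the published component means imply PSI 5*(0.3486+0.2948) = 3.217
        assert 5 * (34.86 + 29.48) / 100 == pytest.approx(3.217)

    def test_additive_identity_every_epoch(self):
        rng = np.random.default_rng(3)
        hr = series_of(Device.HR, rng.uniform(50, 180, 50))
        cbt = series_of(Device.CBT, rng.uniform(36, 39, 50))
        df = strain_series(hr, cbt, reserves(), StrainParameters(clamp=False))
        np.testing.assert_allclose(df["psi"],
                                   0.05 * (df["cardiac"] + df["thermal"]),
                                   rtol=0, atol=1e-12)

    def test_monotone_in_hr_and_cbt(self):
        hr = series_of(Device.HR, np.linspace(50, 185, 20))
        cbt = series_of(Device.CBT, np.linspace(36.0, 39.2, 20))
        df = strain_series(hr, cbt, reserves())
        assert (np.diff(df["psi"]) >= 0).all()

    def test_clamped_psi_bounded_even_above_predicted_peak(self):
        hr = series_of(Device.HR, [30, 250, 300])
        cbt = series_of(Device.CBT, [35.0, 41.0, 42.0])
        df = strain_series(hr, cbt, reserves())
        assert df["psi"].between(0, 10).all()

    def test_lone_stream_epochs_flagged_incomplete(self):
        hr = series_of(Device.HR, [100] * 10)
        cbt = series_of(Device.CBT, [37.0] * 5)  # covers only first 25 min
        df = strain_series(hr, cbt, reserves())
        assert df["complete"].sum() == 1  # 5 one-min CBT samples = 1 epoch
        incomplete = df[~df["complete"]]
        assert incomplete["psi"].isna().all()
        assert incomplete["cardiac"].notna().all()

    def test_zero_reserve_is_degenerate(self):
        hr = series_of(Device.HR, [60])
        cbt = series_of(Device.CBT, [36.0])
        with pytest.raises(ValueError, match="degenerate"):
            strain_series(hr, cbt, ReserveCapacities(50.0, 50.0, 36.0, 39.5))

    def test_matches_brute_force_oracle(self):
        """Ten-epoch fixture against an explicit spreadsheet-style recompute."""
        rng = np.random.default_rng(42)
        hr_vals = rng.uniform(55, 170, 10)
        cbt_vals = rng.uniform(36.1, 38.9, 10)
        hr = series_of(Device.HR, hr_vals, freq="5min")
        cbt = series_of(Device.CBT, cbt_vals, freq="5min")
        res = reserves(rhr=52.0, peak=191.0, t0=36.1)
        df = strain_series(hr, cbt, res)
        for i in range(10):
            cardiac = 100.0 * (hr_vals[i] - 52.0) / (191.0 - 52.0)
            thermal = 100.0 * (cbt_vals[i] - 36.1) / (39.5 - 36.1)
            psi = min(max(5.0 * (cardiac + thermal) / 100.0, 0.0), 10.0)
            assert df["cardiac"].iloc[i] == pytest.approx(cardiac, abs=1e-9)
            assert df["thermal"].iloc[i] == pytest.approx(thermal, abs=1e-9)
            assert df["psi"].iloc[i] == pytest.approx(psi, abs=1e-9)


class TestSummaries:
    def strain_df(self, hr_vals, hours=None):
        n = len(hr_vals)
        ts = pd.date_range("2023-02-06 08:00", periods=n, freq="5min")
        if hours is not None:
            ts = pd.to_datetime([f"2023-02-06 {h:02d}:00" for h in hours])
        return pd.DataFrame({"timestamp": ts, "hr": hr_vals,
                             "cbt": [37.0] * n, "cardiac": [10.0] * n,
                             "thermal": [10.0] * n, "psi": [1.0] * n,
                             "complete": [True] * n})

    def test_constant_hr_zero_cv(self):
        out = daily_strain_summary({"P1": self.strain_df([60.0] * 6)})
        assert out["cv_hr_pct"].iloc[0] == pytest.approx(0.0)

    def test_cv_uses_sample_sd(self):
        out = daily_strain_summary({"P1": self.strain_df([60.0, 80.0])})
        assert out["mean_hr"].iloc[0] == pytest.approx(70.0)
        assert out["cv_hr_pct"].iloc[0] == pytest.approx(20.203, abs=0.001)

    def test_peak_is_max_of_epochs(self):
        out = daily_strain_summary({"P1": self.strain_df([60, 95, 72])})
        assert out["peak_hr"].iloc[0] == 95.0
        assert out["peak_hr"].iloc[0] >= out["mean_hr"].iloc[0]

    def test_diurnal_profile_flat_for_constant_strain(self):
        df = self.strain_df([70.0] * 5, hours=[1, 5, 9, 13, 21])
        prof = diurnal_profile({"P1": df}, stratify_by_sex=False)
        assert len(prof) == 5
        assert (prof["psi"] == 1.0).all()

    def test_single_hour_single_row(self):
        df = self.strain_df([70.0], hours=[14])
        prof = diurnal_profile({"P1": df}, stratify_by_sex=False)
        assert len(prof) == 1
        assert prof["hour"].iloc[0] == 14
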