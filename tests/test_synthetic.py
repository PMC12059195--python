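"""The synthetic-cohort generator: determinism, calibration, ledgers."""

import numpy as np
import pandas as pd
import pytest

from heatwear.core import Device
from heatwear.qc import apply_plausibility_filters
from heatwear.synthetic import (CohortSpec, TruthRecord,
                                inject_missingness_and_artifacts,
                                simulate_actigraphy_sleep, simulate_cohort,
                                simulate_environment, simulate_physiology,
                                simulate_psi_lme_dataset, simulate_study)


class TestCohort:
    def test_default_cohort_is_24_pairs(self):
        spec = CohortSpec.default(seed=0)
        profiles, households = simulate_cohort(spec)
        assert len(profiles) == 48
        assert len(households) == 24
        sexes = pd.Series([p.sex for p in profiles.values()]).value_counts()
        assert sexes["female"] == sexes["male"] == 24

    def test_each_household_holds_one_pair(self):
        from heatwear.core import validate_household_pairs
        profiles, _ = simulate_cohort(CohortSpec.default(seed=1, n_pairs=5))
        validate_household_pairs(profiles.values())

    def test_same_seed_identical_output(self):
        a, _ = simulate_cohort(CohortSpec.default(seed=3, n_pairs=4))
        b, _ = simulate_cohort(CohortSpec.default(seed=3, n_pairs=4))
        assert a == b

    def test_single_pair(self):
        profiles, households = simulate_cohort(CohortSpec.default(seed=0, n_pairs=1))
        assert len(profiles) == 2
        assert len({p.household_id for p in profiles.values()}) == 1

    def test_invalid_pair_count(self):
        with pytest.raises(ValueError):
            CohortSpec.default(seed=0, n_pairs=0)

    def test_ages_within_eligibility_window(self):
        profiles, _ = simulate_cohort(CohortSpec.default(seed=2, n_pairs=24))
        ages = [p.age for p in profiles.values()]
        assert min(ages) >= 20 and max(ages) <= 45

    def test_adding_a_pair_preserves_existing_draws(self):
        small, _ = simulate_cohort(CohortSpec.default(seed=5, n_pairs=2))
        large, _ = simulate_cohort(CohortSpec.default(seed=5, n_pairs=3))
        for pid in small:
            assert small[pid] == large[pid]


class TestEnvironment:
    def test_outdoor_hourly_max_peaks_mid_afternoon(self):
        spec = CohortSpec.default(seed=0, n_pairs=2)
        _, outdoor = simulate_environment(spec, 14)
        od = outdoor.data.copy()
        od["hour"] = od["timestamp"].dt.hour
        od["date"] = od["timestamp"].dt.date
        mean_hourly_max = od.groupby(["date", "hour"])["value"].max() \
                            .groupby("hour").mean()
        assert mean_hourly_max.idxmax() in (14, 15)

    def test_zero_noise_recovers_exact_sinusoid(self):
        spec = CohortSpec.default(seed=0, n_pairs=1)
        spec.config["environment"]["outdoor"]["noise_sd"] = 0.0
        _, outdoor = simulate_environment(spec, 2)
        # full days of a pure sinusoid average exactly to the mesor
        assert outdoor.data["value"].mean() == pytest.approx(19.3, abs=1e-9)
        assert outdoor.data["value"].max() == pytest.approx(19.3 + 5.0, abs=0.05)

    def test_determinism(self):
        spec = CohortSpec.default(seed=9, n_pairs=2)
        i1, o1 = simulate_environment(spec, 3)
        i2, o2 = simulate_environment(spec, 3)
        pd.testing.assert_frame_equal(o1.data, o2.data)
        pd.testing.assert_frame_equal(i1["H01"].data, i2["H01"].data)

    def test_indoor_sits_above_outdoor(self):
        spec = CohortSpec.default(seed=4, n_pairs=24)
        indoor, outdoor = simulate_environment(spec, 7)
        indoor_mean = np.mean([s.data["value"].mean() for s in indoor.values()])
        assert indoor_mean > outdoor.data["value"].mean()


class TestPhysiology:
    def _inputs(self, spec, pid="H01F"):
        profiles, _ = simulate_cohort(spec)
        prof = profiles[pid]
        _, outdoor = simulate_environment(spec)
        _, _, states = simulate_actigraphy_sleep(prof, spec)
        return prof, outdoor, states

    def test_zero_targets_and_noise_give_constant_series(self):
        spec = CohortSpec.default(seed=0, n_pairs=1, n_days=1)
        for sex in ("female", "male"):
            spec.config["physiology"][sex]["target_cardiac_pct"] = 0.0
            spec.config["physiology"][sex]["target_thermal_pct"] = 0.0
        spec.config["physiology"]["hr_noise_sd"] = 0.0
        spec.config["physiology"]["cbt_noise_sd"] = 0.0
        prof, outdoor, states = self._inputs(spec)
        truth = TruthRecord()
        hr, cbt = simulate_physiology(prof, outdoor, states, spec, truth)
        assert hr.data["value"].nunique() == 1
        assert hr.data["value"].iloc[0] == pytest.approx(truth.resting_hr["H01F"])
        assert cbt.data["value"].iloc[0] == pytest.approx(truth.resting_cbt["H01F"])

    def test_determinism(self):
        spec = CohortSpec.default(seed=6, n_pairs=1, n_days=1)
        prof, outdoor, states = self._inputs(spec)
        hr1, _ = simulate_physiology(prof, outdoor, states, spec)
        hr2, _ = simulate_physiology(prof, outdoor, states, spec)
        pd.testing.assert_frame_equal(hr1.data, hr2.data)

    def test_window_coverage_enforced(self):
        spec = CohortSpec.default(seed=0, n_pairs=1, n_days=1)
        prof, outdoor, states = self._inputs(spec)
        with pytest.raises(ValueError, match="cover"):
            simulate_physiology(prof, outdoor, states.iloc[:100], spec)

    def test_female_nightly_cbt_minimum_recovers_calibration(self):
        """Monte-Carlo: the mean per-participant minimum CBT (5-min epochs)
        sits within 0.05 degC of the configured female resting mean.

        Two deployment days are needed so a slept-through night covers the
        pre-dawn nadir; the nadir is only resting-state when asleep."""
        from heatwear.core import EpochGrid, epoch_average
        mins = []
        for seed in range(4):
            spec = CohortSpec.default(seed=seed, n_pairs=25, n_days=2)
            profiles, _ = simulate_cohort(spec)
            _, outdoor = simulate_environment(spec)
            for pid, prof in profiles.items():
                if prof.sex != "female":
                    continue
                _, _, states = simulate_actigraphy_sleep(prof, spec)
                _, cbt = simulate_physiology(prof, outdoor, states, spec)
                mins.append(epoch_average(cbt, EpochGrid(5)).data["value"].min())
        assert np.mean(mins) == pytest.approx(36.11, abs=0.05)


class TestActigraphyGenerator:
    def test_sleep_truth_is_internally_consistent(self, small_spec):
        profiles, _ = simulate_cohort(small_spec)
        _, nights, _ = simulate_actigraphy_sleep(profiles["H01M"], small_spec)
        assert len(nights) == small_spec.n_days - 1
        for nt in nights:
            assert 0 < nt.total_sleep_h < nt.time_in_bed_h

    def test_determinism(self, small_spec):
        profiles, _ = simulate_cohort(small_spec)
        s1, _, _ = simulate_actigraphy_sleep(profiles["H01F"], small_spec)
        s2, _, _ = simulate_actigraphy_sleep(profiles["H01F"], small_spec)
        pd.testing.assert_frame_equal(s1.data, s2.data)


class TestMissingnessAndArtifacts:
    def pristine_hr(self, hours=24):
        from conftest import make_series
        ts = pd.date_range("2023-02-06", periods=hours * 60, freq="60s")
        return make_series(Device.HR, ts, value=np.full(hours * 60, 70.0))

    def test_zero_rates_return_input_unchanged(self):
        spec = CohortSpec.default(seed=0, n_pairs=1)
        spec.config["missingness"]["HR"] = {"failure_prob": 0.0, "gap_prob": 0.0,
                                            "gap_frac_beta": [1, 9], "max_gaps": 3}
        spec.config["artifacts"]["hr_rate"] = 0.0
        truth = TruthRecord()
        out = inject_missingness_and_artifacts(self.pristine_hr(), spec, truth)
        assert len(out) == 24 * 60
        assert truth.gap_ledger == [] and truth.artifact_ledger == []

    def test_certain_failure_empties_series_and_ledgers_it(self):
        spec = CohortSpec.default(seed=0, n_pairs=1)
        spec.config["missingness"]["HR"]["failure_prob"] = 1.0
        truth = TruthRecord()
        out = inject_missingness_and_artifacts(self.pristine_hr(), spec, truth)
        assert len(out) == 0
        assert truth.gap_ledger[0]["kind"] == "failure"

    def test_expected_completeness_matches_gap_fraction(self):
        """Monte-Carlo vs the analytic expectation E[kept] = 1 - E[Beta]."""
        spec = CohortSpec.default(seed=0, n_pairs=1)
        a, b = 4.0, 16.0  # mean gap fraction 0.20
        spec.config["missingness"]["HR"] = {"failure_prob": 0.0, "gap_prob": 1.0,
                                            "gap_frac_beta": [a, b], "max_gaps": 3}
        spec.config["artifacts"]["hr_rate"] = 0.0
        kept = []
        for seed in range(40):
            spec.seed = seed
            out = inject_missingness_and_artifacts(self.pristine_hr(), spec,
                                                   TruthRecord())
            kept.append(len(out) / (24 * 60))
        assert np.mean(kept) == pytest.approx(1 - a / (a + b), abs=0.04)

    def test_qc_removes_essentially_all_injected_artifacts(self, small_study):
        """Artifacts are drawn outside the plausibility bounds, so the QC
        filter recovers >= 99% of the ledgered insertions."""
        truth = small_study.truth
        art = truth.artifact_frame()
        assert len(art) > 0
        removed = 0
        for pid, prof in small_study.profiles.items():
            for device, store in ((Device.HR, small_study.hr),
                                  (Device.CBT, small_study.cbt)):
                clean, _ = apply_plausibility_filters(store[pid], prof)
                mine = art[(art.unit_id == pid) & (art.device == device.value)]
                clean_ts = set(clean.data["timestamp"])
                removed += sum(ts not in clean_ts for ts in mine["timestamp"])
        assert removed / len(art) >= 0.99


class TestPsiLmeDataset:
    ZERO = {k: 0.0 for k in ("beta0", "sex_male", "wbgt", "wbgt_sex", "mvpa",
                             "sleep", "bmi", "fat_mass")}

    def test_all_zero_model_gives_zero_psi(self):
        df, _ = simulate_psi_lme_dataset(self.ZERO, 4, 12, 0.0, 0.0, seed=0)
        assert (df["psi"] == 0).all()

    def test_pure_wbgt_slope(self):
        betas = dict(self.ZERO, wbgt=1.0)
        df, _ = simulate_psi_lme_dataset(betas, 4, 12, 0.0, 0.0, seed=0)
        np.testing.assert_allclose(df["psi"], df["wbgt"], atol=1e-12)

    def test_daytime_only_timestamps(self):
        df, _ = simulate_psi_lme_dataset(self.ZERO, 2, 144, 0.1, 0.1, seed=0)
        tod = df["timestamp"].dt.time
        import datetime
        assert (tod >= datetime.time(6, 30)).all()
        assert (tod < datetime.time(18, 30)).all()

    def test_determinism_and_sd_validation(self):
        d1, _ = simulate_psi_lme_dataset(self.ZERO, 3, 10, 0.5, 0.8, seed=2)
        d2, _ = simulate_psi_lme_dataset(self.ZERO, 3, 10, 0.5, 0.8, seed=2)
        pd.testing.assert_frame_equal(d1, d2)
        with pytest.raises(ValueError):
            simulate_psi_lme_dataset(self.ZERO, 3, 10, -0.1, 0.8, seed=0)


class TestStudyDeterminism:
    def test_same_seed_same_study(self, small_spec, small_study):
        again = simulate_study(small_spec)
        pid = "H01F"
        pd.testing.assert_frame_equal(small_study.hr[pid].data, again.hr[pid].data)
        pd.testing.assert_frame_equal(small_study.act[pid].data, again.act[pid].data)
        pd.testing.assert_frame_equal(small_study.gps[pid], again.gps[pid])
        assert small_study.truth.resting_hr == again.truth.resting_hr
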