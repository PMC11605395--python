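"""Synthetic-cohort generator and event-record dataset tests."""

import numpy as np
import pandas as pd
import pytest

import rilpk as rk
from rilpk.dataset import DatasetError, ObservationTable


class TestDemographics:
    def test_single_female(self):
        spec = rk.CohortSpec(n_subjects=1, fraction_female=1.0, n_rich=0)
        subs = rk.generate_demographics(spec, np.random.default_rng(0))
        assert len(subs) == 1 and subs[0].female

    def test_fraction_female_near_design(self):
        spec = rk.CohortSpec(n_subjects=238)
        subs = rk.generate_demographics(spec, np.random.default_rng(1))
        frac = np.mean([s.female for s in subs])
        assert abs(frac - 0.20) < 0.08  # binomial noise at n=238

    def test_medians_and_ranges(self):
        spec = rk.CohortSpec(n_subjects=10_000)
        subs = rk.generate_demographics(spec, np.random.default_rng(2))
        age = np.array([s.age for s in subs])
        wt = np.array([s.weight for s in subs])
        bmi = np.array([s.bmi for s in subs])
        assert np.median(age) == pytest.approx(46.0, rel=0.05)
        assert np.median(wt) == pytest.approx(78.0, rel=0.05)
        assert np.median(bmi) == pytest.approx(25.4, rel=0.05)
        assert age.min() >= 20 and age.max() <= 79
        assert wt.min() >= 50 and wt.max() <= 126
        assert bmi.min() >= 18.2 and bmi.max() <= 43.3

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            rk.CohortSpec(n_subjects=0)
        with pytest.raises(ValueError):
            rk.CohortSpec(fraction_female=1.5)
        with pytest.raises(ValueError):
            rk.CohortSpec(template="weekly")


class TestRegimen:
    def test_q8w_schedule(self):
        reg = rk.generate_regimen(48.0, "q8w_900")
        im_weeks = [d.time / 168.0 for d in reg if d.route == "im"]
        assert im_weeks == [4, 8, 16, 24, 32, 40, 48]
        assert all(d.amount == 900.0 for d in reg if d.route == "im")
        oral = [d for d in reg if d.route == "oral"]
        assert len(oral) == 28 and oral[0].time == 0.0

    def test_occasion_counter_caps_at_six(self):
        reg = rk.generate_regimen(48.0, "q8w_900")
        occ = [d.occasion for d in reg if d.route == "im"]
        assert occ == [1, 2, 3, 4, 5, 6, 6]

    def test_q4w_template(self):
        reg = rk.generate_regimen(16.0, "q4w_600")
        ims = [d for d in reg if d.route == "im"]
        assert [d.time / 168.0 for d in ims] == [4, 8, 12, 16]
        assert all(d.amount == 600.0 for d in ims)

    def test_zero_horizon_oral_only(self):
        reg = rk.generate_regimen(0.0)
        assert all(d.route == "oral" for d in reg)


class TestSampling:
    def test_rich_subject_interval_samples(self):
        reg = rk.generate_regimen(24.0)
        t = rk.generate_sampling(reg, rich=True, rng=np.random.default_rng(3))
        # 5 samples inside the second injection's interval [wk8, wk16]:
        # pre-dose trough, +1, +2, +4 weeks, and the wk-16 trough
        in_interval = (t >= 8 * 168 - 24) & (t <= 16 * 168)
        assert in_interval.sum() == 5

    def test_empty_regimen_no_samples(self):
        assert len(rk.generate_sampling([], rich=False, rng=np.random.default_rng(0))) == 0

    def test_median_samples_per_subject(self, params, re_bsv3):
        spec = rk.CohortSpec(n_subjects=150)
        table, subjects, _ = rk.generate_cohort(spec, params, re_bsv3, seed=7)
        counts = [len(s.sampling_times) for s in subjects]
        assert np.median(counts) == pytest.approx(4, abs=1)

    def test_troughs_precede_injections(self):
        reg = rk.generate_regimen(24.0)
        t = rk.generate_sampling(reg, rich=False, rng=np.random.default_rng(4))
        im_times = np.array([d.time for d in reg if d.route == "im"])
        for trough, inj in zip(np.sort(t), im_times):
            assert trough <= inj


class TestSimulateObservations:
    def test_no_variability_matches_typical_profile(self, params):
        re0 = rk.RandomEffectsSpec()
        spec = rk.CohortSpec(n_subjects=3, n_rich=0)
        table, subjects, _ = rk.generate_cohort(spec, params, re0, seed=9)
        for s in subjects:
            obs = table.frame[(table.frame.ID == s.id) & (table.frame.EVID == 0)]
            expected = rk.concentration_closed_form(
                s.regimen, params, obs["TIME"].to_numpy()
            )
            np.testing.assert_allclose(obs["DV"].to_numpy(), expected, rtol=1e-10)

    def test_lloq_censoring_flags(self, params, re_bsv3):
        spec = rk.CohortSpec(n_subjects=5, lloq=1e9)  # censor everything
        table, _, _ = rk.generate_cohort(spec, params, re_bsv3, seed=10)
        obs = table.frame[table.frame.EVID == 0]
        assert (obs["BLQ"] == 1).all()

    def test_deterministic_under_seed(self, params, re_bsv3):
        spec = rk.CohortSpec(n_subjects=8)
        t1, _, _ = rk.generate_cohort(spec, params, re_bsv3, seed=11)
        t2, _, _ = rk.generate_cohort(spec, params, re_bsv3, seed=11)
        pd.testing.assert_frame_equal(t1.frame, t2.frame)

    def test_design_summary_matches_study(self, params, re_bsv3):
        # 238 subjects, ~80/20 sex split, concentrations down to LLOQ scale
        spec = rk.CohortSpec()
        table, _, _ = rk.generate_cohort(spec, params, re_bsv3, seed=12)
        assert table.n_subjects == 238
        by_route = table.n_observations_by_route()
        assert by_route["oral"] == 238
        assert 600 <= by_route["im"] <= 1100


class TestDatasetIO:
    def test_round_trip_bit_identical(self, small_cohort, tmp_path):
        table, _, _ = small_cohort
        path = tmp_path / "cohort.csv"
        rk.write_dataset(table, path)
        back = rk.read_dataset(path)
        pd.testing.assert_frame_equal(
            back.frame.reset_index(drop=True), table.frame.reset_index(drop=True),
            check_dtype=False,
        )
        path2 = tmp_path / "cohort2.csv"
        rk.write_dataset(back, path2)
        assert path.read_text() == path2.read_text()

    def test_missing_columns_rejected(self):
        with pytest.raises(DatasetError, match="missing"):
            ObservationTable(pd.DataFrame({"ID": [1], "TIME": [0.0]}))

    def test_observation_before_dose_rejected(self, small_cohort):
        table, _, _ = small_cohort
        df = table.frame.copy()
        row = df[df.EVID == 0].iloc[[0]].copy()
        row["TIME"] = -0.0
        row["ID"] = 999
        bad = pd.concat([row, df], ignore_index=True)
        with pytest.raises(DatasetError, match="precedes any dose"):
            ObservationTable(bad)

    def test_non_monotone_times_rejected(self, small_cohort):
        table, _, _ = small_cohort
        df = table.frame.copy()
        idx = df.index[df.ID == df.ID.iloc[0]]
        df.loc[idx[-1], "TIME"] = -5.0
        df = pd.concat([df.iloc[: idx[-1]], df.iloc[[idx[-1]]]])
        with pytest.raises(DatasetError):
            ObservationTable(df)

    def test_subset_and_resample(self, small_cohort):
        table, _, _ = small_cohort
        ids = table.subject_ids[:3]
        sub = table.subset(ids)
        assert sub.n_subjects == 3
        rep = table.resample([ids[0], ids[0], ids[1]])
        assert rep.n_subjects == 3  # duplicates get fresh ids
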