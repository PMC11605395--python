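"""Estimation-layer tests: Laplace OFV, likelihood-ratio machinery,
shrinkage, bootstrap mechanics.  Heavier end-to-end recovery checks live in
the acceptance tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

import rilpk as rk
from rilpk.dataset import ObservationTable
from rilpk.estimation import EstimationError, stratified_resample


def _one_subject_table(doses, obs, female=False):
    cov = dict(SEX=int(female), AGE=50.0, WT=80.0, BMI=25.0)
    rows = []
    for d in doses:
        rows.append(dict(ID=1, TIME=d.time, EVID=1, AMT=d.amount, ROUTE=d.route,
                         DUR=d.duration, DV=np.nan, MDV=1, OCC=d.occasion, BLQ=0, **cov))
    for t, dv, route in obs:
        rows.append(dict(ID=1, TIME=t, EVID=0, AMT=0.0, ROUTE=route, DUR=0.0,
                         DV=dv, MDV=0, OCC=0, BLQ=0, **cov))
    frame = pd.DataFrame(rows).sort_values(["TIME", "EVID"]).reset_index(drop=True)
    return ObservationTable(frame)


@pytest.fixture(scope="module")
def oral_toy(params):
    doses = [rk.DoseEvent(time=24.0 * d, amount=25.0, route="oral") for d in range(7)]
    return _one_subject_table(doses, [(96.0, 70.0, "oral"), (144.0, 95.0, "oral")])


class TestOfv:
    def test_zero_variance_equals_fixed_effect_likelihood(self, params, oral_toy):
        re0 = rk.RandomEffectsSpec(sigma_add_oral=18.0, sigma_prop_im=0.18)
        got = rk.ofv(oral_toy, params, re0)
        sub = oral_toy.subjects()[0]
        pred = rk.concentration_closed_form(sub.doses, params, sub.obs_time)
        r = sub.obs_dv - pred
        expected = float(np.sum(r**2 / 18.0**2 + np.log(2 * np.pi * 18.0**2)))
        assert got == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("curvature", ["gn", "exact"])
    def test_matches_quadrature_oracle(self, params, oral_toy, curvature):
        """1-subject, 1-eta Laplace OFV vs numerically integrated marginal
        likelihood, within 0.5 units."""
        omega = 0.3
        re1 = rk.RandomEffectsSpec(omega_CL=omega, sigma_add_oral=18.0,
                                   sigma_prop_im=0.18)
        got = rk.ofv(oral_toy, params, re1, curvature=curvature)
        sub = oral_toy.subjects()[0]

        def integrand(eta):
            pred = rk.concentration_closed_form(
                sub.doses, params.with_(CL=params.CL * math.exp(eta)), sub.obs_time
            )
            r = sub.obs_dv - pred
            lik = np.prod(np.exp(-0.5 * r**2 / 324.0) / math.sqrt(2 * np.pi * 324.0))
            return lik * math.exp(-0.5 * eta**2 / omega**2) / (omega * math.sqrt(2 * np.pi))

        integral, _ = quad(integrand, -4, 4, limit=200)
        assert got == pytest.approx(-2.0 * math.log(integral), abs=0.5)

    def test_subject_order_invariance(self, params, re_bsv3, small_cohort):
        table, _, _ = small_cohort
        v1 = rk.ofv(table, params, re_bsv3)
        df = table.frame.copy()
        df["ID"] = df["ID"].map(
            {i: j for i, j in zip(sorted(df.ID.unique()), reversed(sorted(df.ID.unique())))}
        )
        df = df.sort_values(["ID", "TIME", "EVID"]).reset_index(drop=True)
        v2 = rk.ofv(ObservationTable(df), params, re_bsv3)
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_iov_dimensions_evaluate(self, params, re_spec, small_cohort):
        # full published variability incl. IOV on CL: finite OFV
        table, _, _ = small_cohort
        assert np.isfinite(rk.ofv(table, params, re_spec))

    def test_all_censored_subject_is_diagnosed(self, params, re_bsv3):
        doses = [rk.DoseEvent(time=0.0, amount=25.0, route="oral")]
        table = _one_subject_table(doses, [(24.0, 3.0, "oral")])
        table.frame.loc[table.frame.EVID == 0, "BLQ"] = 1
        with pytest.raises(EstimationError, match="subject 1"):
            rk.ofv(table, params, re_bsv3)


class TestFit:
    def test_noise_free_recovery_of_cl(self, params):
        """BSV on CL only, (near) noise-free data: the fitted typical CL is
        the realised geometric mean of the individual clearances to <1%
        (the exact MLE once every subject's eta is pinned by its data)."""
        re_gen = rk.RandomEffectsSpec(omega_CL=0.25,
                                      sigma_add_oral=1e-3, sigma_prop_im=1e-3)
        spec = rk.CohortSpec(n_subjects=12, n_rich=4)
        table, _, truth = rk.generate_cohort(spec, params, re_gen, seed=5)
        res = rk.fit(table, params.with_(CL=5.0), re_gen,
                     estimate=("CL",), compute_se=False, maxiter=60)
        geo_mean = params.CL * np.exp(truth["eta_CL"].mean())
        assert res.estimates["CL"] == pytest.approx(geo_mean, rel=0.01)

    def test_nested_model_ofv_monotone(self, params, re_bsv3, small_cohort):
        table, _, _ = small_cohort
        init = params.with_(CL=5.5, F_im_fast=0.40)
        reduced = rk.fit(table, init, re_bsv3, estimate=("CL",),
                         compute_se=False, maxiter=60)
        fuller = rk.fit(table, reduced.params, re_bsv3,
                        estimate=("CL", "F_im_fast"),
                        compute_se=False, maxiter=60)
        assert fuller.ofv <= reduced.ofv + 0.1

    def test_few_subjects_warns(self, params, re_bsv3, small_cohort):
        table, _, _ = small_cohort
        tiny = table.subset(table.subject_ids[:2])
        with pytest.warns(UserWarning, match="identifiable"):
            rk.fit(tiny, params, re_bsv3, estimate=("CL",),
                   compute_se=False, maxiter=5)


class TestDeltaOfv:
    def test_thresholds(self):
        sig, d, thr = rk.delta_ofv_test(100.0, 89.0, df=1, alpha=0.001)
        assert sig and d == -11.0 and thr == pytest.approx(10.83, abs=0.01)
        sig, _, thr = rk.delta_ofv_test(100.0, 96.17, df=1, alpha=0.05)
        assert not sig and thr == pytest.approx(3.841, abs=0.01)
        # -6 would survive forward (alpha=.05) but not backward (alpha=.01)
        assert rk.delta_ofv_test(100.0, 94.0, 1, 0.05)[0]
        assert not rk.delta_ofv_test(100.0, 94.0, 1, 0.01)[0]

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            rk.delta_ofv_test(1.0, 0.0, df=0)


class TestShrinkage:
    def test_bounds(self):
        assert rk.shrinkage(np.zeros(50), 0.3) == pytest.approx(100.0)
        eb = np.random.default_rng(0).normal(0, 0.3, 200_000)
        assert rk.shrinkage(eb, eb.std(ddof=1)) == pytest.approx(0.0, abs=1e-9)
        with pytest.raises(ValueError):
            rk.shrinkage(np.zeros(5), 0.0)

    def test_rich_design_shrinks_less_than_sparse(self, params, re_bsv3):
        spec_rich = rk.CohortSpec(n_subjects=15, n_rich=15,
                                  median_follow_up_weeks=48.0)
        spec_sparse = rk.CohortSpec(n_subjects=15, n_rich=0,
                                    median_follow_up_weeks=12.0)
        out = {}
        for name, spec in (("rich", spec_rich), ("sparse", spec_sparse)):
            table, _, _ = rk.generate_cohort(spec, params, re_bsv3, seed=31)
            res = rk.fit(table, params, re_bsv3, estimate=(),
                         compute_se=False, maxiter=1)
            out[name] = rk.shrinkage(res.eb_effects("ka_slow"),
                                     re_bsv3.omega_ka_slow)
        assert out["rich"] < out["sparse"]


class TestBootstrap:
    def test_identity_replicate_reproduces_fit(self, params, re_bsv3, small_cohort):
        table, _, _ = small_cohort
        est = ("CL", "omega_CL")
        ref = rk.fit(table, params, re_bsv3, estimate=est,
                     compute_se=False, maxiter=40)
        boot = rk.bootstrap(table, params, re_bsv3, n_replicates=1, seed=0,
                            estimate=est, identity=True, maxiter=40)
        for k in est:
            assert boot.median[k] == pytest.approx(ref.estimates[k], rel=1e-6)

    def test_seeded_reproducibility(self, params, re_bsv3, small_cohort):
        table, _, _ = small_cohort
        kw = dict(n_replicates=3, seed=7, estimate=("CL",), maxiter=25)
        b1 = rk.bootstrap(table, params, re_bsv3, **kw)
        b2 = rk.bootstrap(table, params, re_bsv3, **kw)
        pd.testing.assert_frame_equal(b1.estimates, b2.estimates)

    def test_stratified_resample_preserves_female_count(self):
        rng = np.random.default_rng(3)
        ids = np.arange(1, 21)
        female = ids <= 4
        chosen = stratified_resample(rng, ids, female)
        assert len(chosen) == 20
        assert int(np.isin(chosen, ids[female]).sum()) == 4

    def test_true_cl_inside_ci95(self, params, re_bsv3):
        spec = rk.CohortSpec(n_subjects=25, n_rich=8)
        table, _, _ = rk.generate_cohort(spec, params, re_bsv3, seed=13)
        boot = rk.bootstrap(table, params.with_(CL=5.5), re_bsv3,
                            n_replicates=10, seed=1,
                            estimate=("CL", "omega_CL"), maxiter=30)
        lo, hi = boot.ci95["CL"]
        assert lo < params.CL < hi
        assert boot.n_failed == 0
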