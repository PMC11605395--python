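"""Hierarchical-layer tests: logit-constrained F_im_fast, log-normal
individual parameters, CV conversions, residual error, IOV."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rilpk as rk


class TestFimfast:
    @pytest.mark.parametrize(
        "theta,eta,female,theta_female,expected",
        [
            (0.276, 0.0, False, -0.456, 0.276),
            (0.276, 0.0, True, -0.456, 0.1501),
            (0.5, 0.0, False, 0.0, 0.5),
        ],
    )
    def test_point_values(self, theta, eta, female, theta_female, expected):
        got = rk.fimfast_individual(theta, eta, female, theta_female)
        assert got == pytest.approx(expected, abs=5e-4)

    @given(eta=st.floats(-20, 20), theta=st.floats(0.05, 0.95))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_range_and_monotonicity(self, eta, theta):
        f = rk.fimfast_individual(theta, eta)
        assert 0.0 < f < 1.0
        assert rk.fimfast_individual(theta, eta + 0.1) > f

    def test_invalid_adjusted_fraction(self):
        with pytest.raises(ValueError):
            rk.fimfast_individual(0.6, 0.0, True, 0.8)  # 0.6*1.8 > 1


class TestIndividualParameters:
    def test_zero_effects_identity(self, params):
        eff = rk.IndividualEffects()
        assert rk.individual_parameters(params, eff) == params

    def test_log_scale_effects(self, params):
        eff = rk.IndividualEffects(eta_CL=math.log(2.0))
        assert rk.individual_parameters(params, eff).CL == pytest.approx(2 * params.CL)

    def test_iov_applies_per_occasion(self, params):
        eff = rk.IndividualEffects(eta_CL=0.1, kappa_CL=(0.3, -0.2))
        p1 = rk.individual_parameters(params, eff, occasion=1)
        p2 = rk.individual_parameters(params, eff, occasion=2)
        # two occasions differ in CL by exp(kappa1 - kappa2)
        assert p1.CL / p2.CL == pytest.approx(math.exp(0.3 - (-0.2)))
        # occasion 0 (oral) carries no IOV
        assert rk.individual_parameters(params, eff, occasion=0).CL == pytest.approx(
            params.CL * math.exp(0.1)
        )

    def test_sampled_medians_equal_typical(self, params, re_spec, rng):
        n = 100_000
        cl = params.CL * np.exp(rng.normal(0, re_spec.omega_CL, n))
        assert np.median(cl) == pytest.approx(params.CL, rel=0.02)

    def test_iov_variance_matches_cv(self, re_spec, rng):
        # within-subject log-CL spread across occasions has SD omega_IOV
        # (13% CV reported)
        kappa = rng.normal(0, re_spec.omega_IOV_CL, 200_000)
        assert rk.cv_from_omega(kappa.std()) == pytest.approx(13.0, rel=0.02)


class TestCvConversions:
    def test_zero(self):
        assert rk.cv_from_omega(0.0) == 0.0

    def test_formula_value(self):
        assert rk.cv_from_omega(0.25) == pytest.approx(25.40, abs=0.01)

    @given(cv=st.floats(0.1, 200.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_round_trip(self, cv):
        assert rk.cv_from_omega(rk.omega_from_cv(cv)) == pytest.approx(cv, rel=1e-12)

    def test_published_cl_row_round_trips(self):
        assert rk.cv_from_omega(rk.omega_from_cv(25.9)) == pytest.approx(25.9)


class TestFimfastCv:
    def test_implied_omega_from_reported_cv(self):
        # CV 16.8% at theta 0.276 implies a logit-scale SD of 0.232
        omega = 16.8 / 100.0 / (1.0 - 0.276)
        assert omega == pytest.approx(0.232, abs=5e-4)
        assert rk.fimfast_cv_approx(0.276, omega) == pytest.approx(16.8, abs=0.01)

    def test_zero_omega(self):
        assert rk.fimfast_cv_approx(0.3, 0.0) == 0.0

    def test_against_monte_carlo(self, rng):
        theta, omega = 0.276, 0.232
        f = rk.fimfast_individual(theta, rng.normal(0, omega, 500_000))
        cv_mc = 100.0 * f.std() / f.mean()
        assert rk.fimfast_cv_approx(theta, omega) == pytest.approx(cv_mc, rel=0.10)


class TestResidualError:
    def test_oral_additive(self):
        assert rk.residual_error_variance(1.0, "oral") == pytest.approx(324.0)
        assert rk.residual_error_variance(500.0, "oral") == pytest.approx(324.0)

    def test_im_proportional(self):
        assert rk.residual_error_variance(100.0, "im") == pytest.approx(324.0)
        assert rk.residual_error_variance(0.0, "im") == 0.0

    def test_negative_prediction_rejected(self):
        with pytest.raises(ValueError):
            rk.residual_error_variance(-1.0, "im")


class TestHalfLifeInterval:
    def test_published_interval(self, params):
        lo, hi = rk.quantiles_lognormal_halflife(params.ka_slow, 82.7)
        assert lo == pytest.approx(5.5, abs=0.05)
        assert hi == pytest.approx(59.0, abs=0.5)

    def test_degenerate_and_symmetry(self, params):
        t = rk.terminal_half_life_im(params.ka_slow)
        lo, hi = rk.quantiles_lognormal_halflife(params.ka_slow, 0.0)
        assert lo == hi == pytest.approx(t)
        lo, hi = rk.quantiles_lognormal_halflife(params.ka_slow, 50.0)
        assert lo * hi == pytest.approx(t * t, rel=1e-10)  # log-symmetric
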