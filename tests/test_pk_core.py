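"""Structural-model unit tests: disposition algebra, derived half-lives,
closed-form superposition and its ODE oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rilpk as rk
from rilpk import DoseEvent


def im(t, amt=900.0, occ=1):
    return DoseEvent(time=t, amount=amt, route="im", occasion=occ)


def oral(t, amt=25.0):
    return DoseEvent(time=t, amount=amt, route="oral")


class TestDisposition:
    def test_micro_constants_from_published_set(self, params):
        d = rk.disposition_constants(params)
        assert d.k10 == pytest.approx(6.74 / 277.0)
        assert d.k10 == pytest.approx(0.02433, rel=2e-4)
        assert d.k21 == pytest.approx(0.004863, rel=2e-4)

    def test_one_compartment_limit(self, params):
        d = rk.disposition_constants(params.with_(Q=1e-14))
        assert d.lambda1 == pytest.approx(d.k10, rel=1e-6)
        assert d.lambda2 == pytest.approx(0.0, abs=1e-16)

    @given(
        cl=st.floats(1.0, 20.0), v3=st.floats(50.0, 500.0),
        q=st.floats(0.5, 20.0), v4=st.floats(100.0, 2000.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_vieta_identities(self, cl, v3, q, v4, params):
        d = rk.disposition_constants(params.with_(CL=cl, V3=v3, Q=q, V4=v4))
        assert d.lambda1 * d.lambda2 == pytest.approx(d.k10 * d.k21, rel=1e-10)
        assert d.lambda1 + d.lambda2 == pytest.approx(d.k10 + d.k12 + d.k21, rel=1e-10)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            rk.PKParameters(CL=-1, V3=277, Q=4, V4=839, ka_fast=2e-3,
                            ka_slow=2e-4, F_im_fast=0.3, F_oral=0.6, D_oral=4)
        with pytest.raises(ValueError):
            rk.PKParameters(CL=6.7, V3=277, Q=4, V4=839, ka_fast=2e-3,
                            ka_slow=2e-4, F_im_fast=1.2, F_oral=0.6, D_oral=4)


class TestDerivedQuantities:
    def test_half_lives_independent_of_bioavailability(self, params):
        a = rk.biphasic_half_lives(params)
        b = rk.biphasic_half_lives(params.with_(F_oral=0.1))
        assert a == b

    def test_terminal_half_life_units(self):
        # ln2/168 per hour is by construction a one-week half-life
        assert rk.terminal_half_life_im(np.log(2) / 168.0) == pytest.approx(1.0)
        assert rk.terminal_half_life_im(0.00214) == pytest.approx(1.93, abs=0.01)

    def test_flip_flop_violation_warns(self, params):
        with pytest.warns(UserWarning):
            rk.terminal_half_life_im(1.0, params)

    def test_time_to_steady_state_proportionality(self):
        base = rk.time_to_steady_state(4e-4)
        assert rk.time_to_steady_state(2e-4) == pytest.approx(2 * base)
        assert rk.time_to_steady_state(4e-4, n_half_lives=0) == 0.0

    def test_degenerate_terminal_phase_is_error(self, params):
        with pytest.raises(ValueError):
            rk.biphasic_half_lives(params.with_(Q=0.0))


class TestClosedForm:
    def test_superposition_of_simultaneous_doses(self, params):
        t = np.linspace(0, 5000, 60)
        one = rk.concentration_closed_form([im(0, 1800)], params, t)
        two = rk.concentration_closed_form([im(0, 900), im(0, 900)], params, t)
        np.testing.assert_allclose(one, two, rtol=1e-12)

    def test_linearity_in_dose(self, params):
        t = np.linspace(0, 5000, 60)
        ref = rk.concentration_closed_form([im(0, 900), oral(100, 25)], params, t)
        x3 = rk.concentration_closed_form([im(0, 2700), oral(100, 75)], params, t)
        np.testing.assert_allclose(x3, 3 * ref, rtol=1e-12)

    def test_zero_before_first_dose(self, params):
        c = rk.concentration_closed_form([im(100.0)], params, np.array([0.0, 50.0, 99.9]))
        assert np.all(c == 0.0)

    def test_terminal_slope_is_slow_absorption_rate(self, params):
        # flip-flop: fitted log-slope over weeks 20-100 after a single
        # injection equals -ka_slow within 1%
        t = np.linspace(20 * 168.0, 100 * 168.0, 200)
        c = rk.concentration_closed_form([im(0.0)], params, t)
        slope = np.polyfit(t, np.log(c), 1)[0]
        assert -slope == pytest.approx(params.ka_slow, rel=0.01)

    def test_oral_steady_state_average(self, params):
        # C_avg at steady state = F·dose/(CL·tau); trough below average
        reg = [oral(24.0 * d) for d in range(120)]
        t_avg = np.linspace(119 * 24.0, 120 * 24.0, 100)
        c = rk.concentration_closed_form(reg, params, t_avg)
        c_avg = 25000.0 * params.F_oral / (params.CL * 24.0)
        assert c.mean() == pytest.approx(c_avg, rel=0.02)
        assert c.min() < c_avg < c.max()

    def test_unknown_route_rejected(self):
        with pytest.raises(ValueError):
            DoseEvent(time=0.0, amount=1.0, route="intrathecal")


class TestOdeOracle:
    def test_agreement_on_standard_regimen(self, params):
        reg = rk.generate_regimen(48.0)
        t = np.linspace(1.0, 56 * 168.0, 150)
        cf = rk.concentration_closed_form(reg, params, t)
        ode = rk.concentration_ode(reg, params, t)
        assert np.max(np.abs(cf - ode) / np.maximum(np.abs(ode), 1e-9)) < 1e-3

    def test_agreement_over_random_draws(self, params, rng):
        # random parameter sets within ±50% of the published values, random
        # small regimens: closed form vs ODE < 0.1% relative
        worst = 0.0
        for _ in range(60):
            f = lambda v: v * rng.uniform(0.5, 1.5)
            pr = rk.PKParameters(
                CL=f(6.74), V3=f(277.0), Q=f(4.08), V4=f(839.0),
                ka_fast=f(0.00214), ka_slow=f(0.000229),
                F_im_fast=min(0.9, f(0.276)), F_oral=min(1.0, f(0.654)),
                D_oral=4.0,
            )
            reg = [im(0.0)]
            if rng.random() < 0.5:
                reg.append(im(rng.uniform(500, 2000), 600.0, occ=2))
            if rng.random() < 0.5:
                reg.insert(0, oral(0.0))
                reg.sort(key=lambda d: d.time)
            t = np.sort(rng.uniform(1.0, 8000.0, 40))
            cf = rk.concentration_closed_form(reg, pr, t)
            ode = rk.concentration_ode(reg, pr, t)
            worst = max(worst, np.max(np.abs(cf - ode) / np.maximum(np.abs(ode), 1e-9)))
        assert worst < 1e-3

    def test_mass_conservation(self, params):
        reg = [oral(0.0), oral(24.0), im(48.0)]
        t = np.linspace(0.5, 4000, 50)
        _, extra = rk.concentration_ode(reg, params, t, full_output=True)
        in_system = extra["states"][:, :4].sum(axis=1)
        eliminated = extra["states"][:, 4]
        np.testing.assert_allclose(
            in_system + eliminated, extra["administered"], rtol=1e-8, atol=1e-6
        )

    def test_empty_regimen_all_zero(self, params):
        np.testing.assert_array_equal(
            rk.concentration_ode([], params, np.linspace(0, 100, 5)), 0.0
        )
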