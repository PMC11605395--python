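import warnings

import numpy as np
import pytest

import rilpk as rk

# exp over/underflow inside damped inner-Newton trial steps is expected and
# handled; don't let it clutter test output
warnings.filterwarnings("ignore", category=RuntimeWarning, message="overflow")


@pytest.fixture(scope="session")
def params():
    return rk.published_parameters()


@pytest.fixture(scope="session")
def re_spec():
    return rk.published_random_effects()


@pytest.fixture(scope="session")
def re_bsv3():
    """BSV on the three structural targets + residual error (no IOV, no
    F_oral BSV) — the variability layer of the recovery experiments."""
    return rk.RandomEffectsSpec(
        omega_ka_slow=rk.omega_from_cv(82.7),
        omega_CL=rk.omega_from_cv(25.9),
        omega_eta_Ffast=0.232,
        sigma_add_oral=18.0,
        sigma_prop_im=0.18,
    )


@pytest.fixture(scope="session")
def small_cohort(params, re_bsv3):
    """A 20-subject study-design cohort shared by the cheap estimation and
    dataset tests."""
    spec = rk.CohortSpec(n_subjects=20, n_rich=4)
    table, subjects, truth = rk.generate_cohort(spec, params, re_bsv3, seed=42)
    return table, subjects, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
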