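"""Hierarchical (population) layer of the rilpivirine model.

Maps typical parameters + random effects + covariates to individual
parameters, defines the residual-error models, and provides the CV%
conversions used to report variability.

Random-effect conventions
-------------------------
* CL, F_oral and ka_slow carry log-normal between-subject variability:
  ``p_i = p_typ · exp(eta)``.  F_oral is deliberately not truncated at 1;
  sampled values above 1 are read as oral exposure exceeding the IM-relative
  reference for that subject.
* F_im_fast varies on the logit scale so individual fractions stay in (0,1).
* Clearance additionally carries an inter-occasion effect: a fresh
  ``kappa`` is drawn for each injection occasion (1..6), log-additive with
  the subject's eta.
* Residual error: additive (ng/mL) for oral observations, proportional for
  IM observations.
"""

from __future__ import annotations

import math

import numpy as np

from .params import (
    PKParameters,
    RandomEffectsSpec,
    CovariateModel,
    IndividualEffects,
    HOURS_PER_WEEK,
)
from .pk_core import MAX_OCCASIONS, LN2

__all__ = [
    "fimfast_individual",
    "individual_parameters",
    "sample_effects",
    "cv_from_omega",
    "omega_from_cv",
    "fimfast_cv_approx",
    "residual_error_variance",
    "quantiles_lognormal_halflife",
]


def fimfast_individual(theta: float, eta=0.0, female=False, theta_female: float = 0.0):
    """Individual fast-pathway fraction, constrained to (0, 1).

    The typical fraction ``theta`` (optionally scaled by
    ``1 + theta_female`` for females) is transformed to the logit scale,
    the subject's eta is added there, and the inverse logit maps back:

        TEMP = ln(θ* / (1 − θ*)),  θ* = θ·(1 + θ_female·female)
        F_i  = exp(TEMP + η) / (1 + exp(TEMP + η))

    Accepts array-valued ``eta``/``female`` and broadcasts.
    """
    female = np.asarray(female, dtype=float)
    theta_star = theta * (1.0 + theta_female * female)
    if np.any(theta_star <= 0.0) or np.any(theta_star >= 1.0):
        raise ValueError("covariate-adjusted fraction must remain inside (0, 1)")
    temp = np.log(theta_star / (1.0 - theta_star))
    z = temp + np.asarray(eta, dtype=float)
    out = 1.0 / (1.0 + np.exp(-z))
    if out.ndim == 0:
        return float(out)
    return out


def individual_parameters(
    typical: PKParameters,
    effects: IndividualEffects,
    occasion: int = 0,
    female: bool = False,
    covariate_model: CovariateModel | None = None,
) -> PKParameters:
    """Parameters of one subject at one injection occasion.

    CL_i = CL·exp(eta_CL + kappa_occ); F_oral and ka_slow are log-normal;
    F_im_fast goes through :func:`fimfast_individual`.  V3, Q, V4, ka_fast
    and D_oral have no between-subject variability in this model.
    """
    theta_female = covariate_model.theta_female if covariate_model is not None else 0.0
    return typical.with_(
        CL=typical.CL * math.exp(effects.eta_CL + effects.kappa_for(occasion)),
        F_oral=typical.F_oral * math.exp(effects.eta_F_oral),
        ka_slow=typical.ka_slow * math.exp(effects.eta_ka_slow),
        F_im_fast=fimfast_individual(
            typical.F_im_fast, effects.eta_Ffast, female, theta_female
        ),
    )


def sample_effects(
    re_spec: RandomEffectsSpec, rng: np.random.Generator, n_occasions: int = MAX_OCCASIONS
) -> IndividualEffects:
    """Draw one subject's random effects (diagonal Omega, fresh IOV per occasion)."""
    return IndividualEffects(
        eta_F_oral=rng.normal(0.0, re_spec.omega_F_oral),
        eta_ka_slow=rng.normal(0.0, re_spec.omega_ka_slow),
        eta_CL=rng.normal(0.0, re_spec.omega_CL),
        eta_Ffast=rng.normal(0.0, re_spec.omega_eta_Ffast),
        kappa_CL=tuple(rng.normal(0.0, re_spec.omega_IOV_CL, size=n_occasions)),
    )


def cv_from_omega(omega):
    """CV% of a log-normal effect: 100·sqrt(exp(ω²) − 1)."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega must be >= 0")
    out = 100.0 * np.sqrt(np.expm1(omega * omega))
    return float(out) if out.ndim == 0 else out


def omega_from_cv(cv_percent):
    """Inverse of :func:`cv_from_omega`: ω = sqrt(ln(1 + (CV/100)²))."""
    cv = np.asarray(cv_percent, dtype=float) / 100.0
    if np.any(cv < 0):
        raise ValueError("CV must be >= 0")
    out = np.sqrt(np.log1p(cv * cv))
    return float(out) if out.ndim == 0 else out


def fimfast_cv_approx(theta: float, omega_eta: float) -> float:
    """Delta-method CV% of the logistic-transformed F_im_fast.

    SD(F) ≈ θ(1−θ)·ω on the natural scale, so CV% ≈ 100·(1−θ)·ω.  Good to
    ~10% relative for ω ≲ 0.3; the exact CV is available by Monte Carlo.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie in (0, 1)")
    if omega_eta < 0:
        raise ValueError("omega_eta must be >= 0")
    return 100.0 * (1.0 - theta) * omega_eta


def residual_error_variance(pred, route):
    """Observation variance (ng/mL)² at a model prediction.

    Oral records: additive, σ_add²; IM records: proportional, (σ_prop·pred)².
    ``route`` is 'oral' or 'im'; broadcasts over array predictions.
    """
    from .params import published_random_effects

    return residual_variance(pred, route, published_random_effects())


def residual_variance(pred, route, re_spec: RandomEffectsSpec):
    pred = np.asarray(pred, dtype=float)
    if np.any(pred < 0):
        raise ValueError("predictions must be >= 0")
    if route == "oral":
        out = np.full_like(pred, re_spec.sigma_add_oral ** 2)
    elif route == "im":
        out = (re_spec.sigma_prop_im * pred) ** 2
    else:
        raise ValueError(f"unknown route {route!r}")
    return float(out) if out.ndim == 0 else out


def quantiles_lognormal_halflife(
    ka_slow: float, cv_percent: float, level: float = 0.90
) -> tuple[float, float]:
    """Population interval of the individual IM terminal half-life, in weeks.

    ka_slow is log-normal across subjects, hence so is t½ = ln2/ka_slow.
    With σ = sqrt(ln(1 + CV²)) the central ``level`` interval is
    t½_typ · exp(∓z·σ), symmetric on the log scale about the typical value.
    """
    from scipy.stats import norm

    if cv_percent < 0:
        raise ValueError("CV must be >= 0")
    t_half_weeks = LN2 / ka_slow / HOURS_PER_WEEK
    sigma = omega_from_cv(cv_percent)
    z = norm.ppf(0.5 + level / 2.0)
    return t_half_weeks * math.exp(-z * sigma), t_half_weeks * math.exp(z * sigma)
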