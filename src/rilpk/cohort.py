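"""Synthetic study cohorts emulating the observational design.

The real dataset (a Swiss HIV cohort therapeutic-drug-monitoring study) is
access-restricted, so every downstream stage is exercised on generated
cohorts that mimic its design: 238 subjects, 80%/20% male/female, oral
25 mg daily lead-in for 4 weeks, a 900 mg IM loading injection at week 4
and week 8 followed by maintenance injections every 8 weeks (template
``q8w_900``; a monthly 600 mg template ``q4w_600`` covers the
compassionate-use schedule), sparse pre-injection trough sampling with a
median of ~4 samples per subject, a rich-sampling subset measured 1/2/4/8
weeks after one injection, and censoring at the 5 ng/mL quantification
limit.

Observed concentrations are produced from the structural model with the
full hierarchical layer (BSV, per-injection IOV on clearance, route-
specific residual error); the generating random effects are returned as a
truth table for recovery experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import (
    PKParameters,
    RandomEffectsSpec,
    CovariateModel,
    IndividualEffects,
    HOURS_PER_WEEK,
)
from .pk_core import DoseEvent, MAX_OCCASIONS, superpose_profile
from .population import sample_effects, fimfast_individual
from .dataset import ObservationTable, REQUIRED_COLUMNS

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "generate_demographics",
    "generate_regimen",
    "generate_sampling",
    "simulate_observations",
    "generate_cohort",
    "REGIMEN_TEMPLATES",
]

#: dose (mg) and maintenance interval (weeks) per regimen template; the
#: loading phase is two injections 4 weeks apart starting at the end of
#: the oral lead-in.
REGIMEN_TEMPLATES = {
    "q8w_900": {"im_dose": 900.0, "interval_weeks": 8.0},
    "q4w_600": {"im_dose": 600.0, "interval_weeks": 4.0},
}


@dataclass
class CohortSpec:
    """Design of a synthetic cohort (defaults = study design)."""

    n_subjects: int = 238
    fraction_female: float = 0.20
    n_rich: int = 28
    lloq: float = 5.0              # ng/mL
    template: str = "q8w_900"
    oral_dose_mg: float = 25.0     # standard oral rilpivirine dose, daily
    lead_in_weeks: float = 4.0
    median_follow_up_weeks: float = 26.0
    log_sd_follow_up: float = 0.75
    follow_up_range: tuple = (4.0, 96.0)
    sampling_jitter: float = 0.10  # fraction of the elapsed interval

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.fraction_female <= 1.0:
            raise ValueError("fraction_female must lie in [0, 1]")
        if self.lloq <= 0:
            raise ValueError("lloq must be > 0")
        if self.template not in REGIMEN_TEMPLATES:
            raise ValueError(f"unknown regimen template {self.template!r}")


@dataclass
class SubjectRecord:
    id: int
    female: bool
    age: float
    weight: float
    bmi: float
    follow_up_weeks: float = 26.0
    rich: bool = False
    regimen: list = field(default_factory=list)
    sampling_times: np.ndarray = None
    effects: IndividualEffects | None = None


# demographics: median (low, high) from the study population table
_DEMOGRAPHICS = {
    "age": (46.0, 20.0, 79.0),
    "weight": (78.0, 50.0, 126.0),
    "bmi": (25.4, 18.2, 43.3),
}


def _truncated_lognormal(rng, median, lo, hi, size):
    """Lognormal with the given median, truncated to [lo, hi] by resampling.

    The log-SD is set so the stated range corresponds to roughly ±2.7 SD,
    which reproduces the published medians and ranges without implying a
    joint weight–BMI model.
    """
    sigma = (math.log(hi) - math.log(lo)) / 5.4
    out = np.empty(size)
    need = np.ones(size, dtype=bool)
    while need.any():
        draw = rng.lognormal(math.log(median), sigma, size=int(need.sum()))
        ok = (draw >= lo) & (draw <= hi)
        idx = np.where(need)[0][ok]
        out[idx] = draw[ok]
        need[idx] = False
    return out


def generate_demographics(spec: CohortSpec, rng: np.random.Generator) -> list[SubjectRecord]:
    """Draw subjects' sex, age, weight and BMI (independent draws)."""
    n = spec.n_subjects
    female = rng.random(n) < spec.fraction_female
    age = _truncated_lognormal(rng, *_DEMOGRAPHICS["age"], n)
    wt = _truncated_lognormal(rng, *_DEMOGRAPHICS["weight"], n)
    bmi = _truncated_lognormal(rng, *_DEMOGRAPHICS["bmi"], n)
    fu = np.clip(
        rng.lognormal(math.log(spec.median_follow_up_weeks), spec.log_sd_follow_up, n),
        *spec.follow_up_range,
    )
    rich = np.zeros(n, dtype=bool)
    rich[rng.choice(n, size=min(spec.n_rich, n), replace=False)] = True
    # rich subjects need one complete maintenance interval to sample
    interval = REGIMEN_TEMPLATES[spec.template]["interval_weeks"]
    fu[rich] = np.maximum(fu[rich], spec.lead_in_weeks + 4.0 + 2 * interval)
    return [
        SubjectRecord(
            id=i + 1, female=bool(female[i]), age=float(age[i]),
            weight=float(wt[i]), bmi=float(bmi[i]),
            follow_up_weeks=float(fu[i]), rich=bool(rich[i]),
        )
        for i in range(n)
    ]


def generate_regimen(
    follow_up_weeks: float,
    template: str = "q8w_900",
    oral_dose_mg: float = 25.0,
    lead_in_weeks: float = 4.0,
) -> list[DoseEvent]:
    """Dose events of the standard schedule up to the follow-up horizon.

    Daily oral doses through the lead-in, a loading injection at the end of
    the lead-in, a second injection 4 weeks later, then maintenance
    injections every template interval.  The injection occasion counter
    increments per injection and is capped at :data:`MAX_OCCASIONS`.
    """
    if template not in REGIMEN_TEMPLATES:
        raise ValueError(f"unknown regimen template {template!r}")
    tpl = REGIMEN_TEMPLATES[template]
    doses = [
        DoseEvent(time=24.0 * d, amount=oral_dose_mg, route="oral")
        for d in range(int(lead_in_weeks * 7))
    ]
    week = lead_in_weeks
    occ = 0
    while week <= follow_up_weeks:
        occ += 1
        doses.append(
            DoseEvent(
                time=week * HOURS_PER_WEEK, amount=tpl["im_dose"], route="im",
                occasion=min(occ, MAX_OCCASIONS),
            )
        )
        week += 4.0 if occ == 1 else tpl["interval_weeks"]
    return doses


def generate_sampling(
    regimen: list[DoseEvent],
    rich: bool,
    rng: np.random.Generator,
    jitter: float = 0.10,
) -> np.ndarray:
    """Sampling times (h) for one subject.

    Sparse design: one oral trough immediately before the loading
    injection plus a trough immediately before every later injection.
    Rich design adds samples 1, 2 and 4 weeks after the second injection
    (the 8-week trough being the next pre-injection sample).  Nominal
    times are jittered by ±``jitter`` of the elapsed interval to emulate
    real-world visit variation; pre-injection samples are only moved
    earlier so they stay troughs.
    """
    if not regimen:
        return np.array([])
    times = []
    dose_times = np.array([d.time for d in regimen])
    im_times = np.array([d.time for d in regimen if d.route == "im"])
    for t_inj in im_times:
        prev = dose_times[dose_times < t_inj]
        gap = t_inj - (prev.max() if len(prev) else 0.0)
        times.append(t_inj - rng.uniform(0.0, jitter) * gap)
    if rich and len(im_times) >= 2:
        t2 = im_times[1]
        nxt = im_times[im_times > t2]
        t_end = nxt.min() if len(nxt) else np.inf
        for w in (1.0, 2.0, 4.0):
            off = w * HOURS_PER_WEEK * (1.0 + rng.uniform(-jitter, jitter))
            t = t2 + off
            if t < t_end:
                times.append(t)
    return np.sort(np.array(times))


def _route_occ_at(doses: list[DoseEvent], t: float) -> tuple[str, int]:
    """Route of the last dose strictly before t and occasion of the last IM
    dose.  A sample drawn at exactly an injection time is a pre-dose trough
    and belongs to the preceding dose's route."""
    route, occ = "oral", 0
    for d in doses:
        if d.time >= t:
            break
        route = d.route
        if d.route == "im":
            occ = d.occasion
    return route, occ


def simulate_observations(
    subjects: list[SubjectRecord],
    params: PKParameters,
    re_spec: RandomEffectsSpec,
    rng: np.random.Generator,
    covariate_model: CovariateModel | None = None,
    lloq: float = 5.0,
) -> tuple[ObservationTable, pd.DataFrame]:
    """Observed concentrations for a cohort with regimens and sampling set.

    Each subject's true profile uses their sampled random effects; the
    clearance acting on a dose is the occasion-specific CL of the occasion
    the dose was given in (dose-wise superposition).  Route-specific
    residual noise is added; values below ``lloq`` are written with a BLQ
    flag (and clipped at 0 when the noise drives them negative).

    Returns the event table and a truth frame of the generating effects.
    """
    theta_female = covariate_model.theta_female if covariate_model is not None else 0.0
    rows = []
    truth = []
    for s in subjects:
        if s.effects is None:
            s.effects = sample_effects(re_spec, rng)
        eff = s.effects
        doses = s.regimen
        dt = np.array([d.time for d in doses])
        da = np.array([d.amount for d in doses])
        d_oral = np.array([d.route == "oral" for d in doses])
        ddur = np.array([d.duration for d in doses])
        kappa = np.array([eff.kappa_for(d.occasion) for d in doses])
        cl_dose = params.CL * np.exp(eff.eta_CL + kappa)
        f_fast = fimfast_individual(
            params.F_im_fast, eff.eta_Ffast, s.female, theta_female
        )
        t_obs = np.asarray(s.sampling_times, dtype=float)
        if len(t_obs):
            pred = superpose_profile(
                t_obs, dt, da, d_oral, ddur,
                CL=cl_dose, V3=params.V3, Q=params.Q, V4=params.V4,
                ka_fast=params.ka_fast,
                ka_slow=params.ka_slow * math.exp(eff.eta_ka_slow),
                F_im_fast=f_fast,
                F_oral=params.F_oral * math.exp(eff.eta_F_oral),
                D_oral=params.D_oral,
            )
        else:
            pred = np.array([])

        cov = dict(SEX=int(s.female), AGE=round(s.age, 1),
                   WT=round(s.weight, 1), BMI=round(s.bmi, 1))
        for d in doses:
            rows.append(dict(ID=s.id, TIME=d.time, EVID=1, AMT=d.amount,
                             ROUTE=d.route, DUR=d.duration, DV=np.nan, MDV=1,
                             OCC=d.occasion, BLQ=0, **cov))
        for t, p in zip(t_obs, pred):
            route, occ = _route_occ_at(doses, t)
            if route == "oral":
                dv = p + rng.normal(0.0, re_spec.sigma_add_oral)
            else:
                dv = p * (1.0 + rng.normal(0.0, re_spec.sigma_prop_im))
            blq = int(dv < lloq)
            rows.append(dict(ID=s.id, TIME=t, EVID=0, AMT=0.0, ROUTE=route,
                             DUR=0.0, DV=max(dv, 0.0), MDV=0, OCC=occ,
                             BLQ=blq, **cov))
        truth.append(dict(
            ID=s.id, female=int(s.female), age=s.age, weight=s.weight,
            bmi=s.bmi, eta_CL=eff.eta_CL, eta_F_oral=eff.eta_F_oral,
            eta_ka_slow=eff.eta_ka_slow, eta_Ffast=eff.eta_Ffast,
            CL_i=params.CL * math.exp(eff.eta_CL),
            F_im_fast_i=f_fast,
            ka_slow_i=params.ka_slow * math.exp(eff.eta_ka_slow),
            **{f"kappa_{k+1}": (eff.kappa_CL[k] if k < len(eff.kappa_CL) else 0.0)
               for k in range(MAX_OCCASIONS)},
        ))

    frame = pd.DataFrame(rows, columns=REQUIRED_COLUMNS)
    frame = frame.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)
    return ObservationTable(frame), pd.DataFrame(truth)


def generate_cohort(
    spec: CohortSpec,
    params: PKParameters,
    re_spec: RandomEffectsSpec,
    seed: int,
    covariate_model: CovariateModel | None = None,
):
    """End-to-end cohort generation under a single seed.

    Returns (ObservationTable, subjects, truth_frame).  Identical seeds
    yield identical tables.
    """
    rng = np.random.default_rng(seed)
    subjects = generate_demographics(spec, rng)
    for s in subjects:
        s.regimen = generate_regimen(
            s.follow_up_weeks, spec.template, spec.oral_dose_mg, spec.lead_in_weeks
        )
        s.sampling_times = generate_sampling(
            s.regimen, s.rich, rng, spec.sampling_jitter
        )
    table, truth = simulate_observations(
        subjects, params, re_spec, rng, covariate_model, spec.lloq
    )
    return table, subjects, truth
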