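"""Deterministic structural PK model for oral and long-acting IM rilpivirine.

Two-compartment disposition (central V3, peripheral V4, clearances CL and Q)
with two input routes:

* oral — zero-order (constant-rate) input of ``amount · F_oral`` directly
  into the central compartment over ``D_oral`` hours;
* intramuscular — the dose splits at injection time into a fast depot
  (fraction ``F_im_fast``, rate ``ka_fast``) and a slow depot
  (``1 − F_im_fast``, rate ``ka_slow``), each draining first-order into the
  central compartment.  IM bioavailability is 1 by definition.

Because ka_slow is far below the terminal disposition rate, the system shows
flip-flop kinetics: the terminal plasma slope after an injection is −ka_slow,
and the apparent IM half-life is an absorption half-life.

The model is linear, so arbitrary regimens are evaluated by closed-form
superposition of single-dose solutions (bi-exponential for zero-order input,
tri-exponential for first-order depot input).  A numerical ODE solution of
the same system serves as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import PKParameters, HOURS_PER_WEEK, HOURS_PER_YEAR

__all__ = [
    "DoseEvent",
    "DispositionConstants",
    "disposition_constants",
    "biphasic_half_lives",
    "terminal_half_life_im",
    "time_to_steady_state",
    "concentration_closed_form",
    "concentration_ode",
    "superpose_profile",
    "MAX_OCCASIONS",
]

LN2 = math.log(2.0)
MG_TO_UG = 1000.0
#: occasions (injections) beyond the sixth share the sixth occasion's IOV effect
MAX_OCCASIONS = 6

ROUTE_ORAL = "oral"
ROUTE_IM = "im"


@dataclass(frozen=True)
class DoseEvent:
    """One administration event.

    time is hours since the first dose of the regimen; amount in mg.
    ``duration`` is the zero-order input length for oral doses (0 means
    "use the model's D_oral") and must be 0 for IM doses.  ``occasion``
    is the 1-based injection counter for IM doses (capped at
    :data:`MAX_OCCASIONS`); oral doses belong to occasion 0 and carry no
    inter-occasion variability.
    """

    time: float
    amount: float
    route: str
    duration: float = 0.0
    occasion: int = 0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.amount <= 0:
            raise ValueError("dose amount must be > 0")
        if self.route not in (ROUTE_ORAL, ROUTE_IM):
            raise ValueError(f"unknown route {self.route!r}; expected 'oral' or 'im'")
        if self.route == ROUTE_IM and self.duration != 0.0:
            raise ValueError("IM doses are instantaneous depot deposits (duration 0)")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")


@dataclass(frozen=True)
class DispositionConstants:
    """Micro-constants and macro eigenvalues of two-compartment disposition.

    Satisfies the Vieta identities lambda1·lambda2 = k10·k21 and
    lambda1 + lambda2 = k10 + k12 + k21.
    """

    k10: float
    k12: float
    k21: float
    lambda1: float
    lambda2: float


def disposition_constants(params: PKParameters) -> DispositionConstants:
    """Micro rate constants and the two disposition eigenvalues.

    k10 = CL/V3, k12 = Q/V3, k21 = Q/V4; the eigenvalues are the roots of
    s² − (k10+k12+k21)s + k10·k21, ordered lambda1 > lambda2 ≥ 0.
    """
    k10 = params.CL / params.V3
    k12 = params.Q / params.V3
    k21 = params.Q / params.V4
    s = k10 + k12 + k21
    # sqrt of the discriminant written to stay accurate when k21 << k10
    disc = math.sqrt(max((s * s) - 4.0 * k10 * k21, 0.0))
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    if lam1 > 0.0:  # refine lam2 via the product to avoid cancellation
        lam2 = k10 * k21 / lam1
    return DispositionConstants(k10=k10, k12=k12, k21=k21, lambda1=lam1, lambda2=lam2)


def biphasic_half_lives(params: PKParameters) -> tuple[float, float]:
    """Distribution and terminal half-lives (h) of the disposition system.

    These are the two phases visible after oral dosing: an initial decline
    driven by distribution into the peripheral compartment plus onset of
    elimination (ln2/lambda1) and a terminal decline after pseudo-
    equilibrium (ln2/lambda2).  Bioavailability cancels and does not enter.
    """
    d = disposition_constants(params)
    if d.lambda2 <= 0.0:
        raise ValueError("lambda2 = 0: system has no terminal elimination phase")
    return LN2 / d.lambda1, LN2 / d.lambda2


def terminal_half_life_im(ka_slow: float, params: PKParameters | None = None) -> float:
    """Apparent terminal half-life (weeks) of the long-acting injectable.

    Under flip-flop kinetics the terminal slope equals the slow absorption
    rate constant, so t½ = ln2/ka_slow.  When ``params`` is supplied the
    flip-flop ordering ka_slow < lambda2 (and < k10) is checked and a
    warning is emitted if it fails; the value is returned regardless.
    """
    if ka_slow <= 0:
        raise ValueError("ka_slow must be > 0")
    if params is not None:
        import warnings

        d = disposition_constants(params)
        if not (ka_slow < d.lambda2 and ka_slow < d.k10):
            warnings.warn(
                "no flip-flop: ka_slow is not below the disposition rates; "
                "the terminal slope will not reflect absorption",
                stacklevel=2,
            )
    return LN2 / ka_slow / HOURS_PER_WEEK


def time_to_steady_state(ka_slow: float, n_half_lives: float = 5.0) -> float:
    """Years until the injectable reaches steady state.

    Uses the conventional ``n_half_lives`` × terminal half-life rule (the
    rate-limiting constant being ka_slow); default 5 half-lives ≈ 97%
    of steady state.
    """
    if ka_slow <= 0:
        raise ValueError("ka_slow must be > 0")
    return n_half_lives * LN2 / ka_slow / HOURS_PER_YEAR


# ---------------------------------------------------------------------------
# Closed-form superposition
# ---------------------------------------------------------------------------

def superpose_profile(
    times,
    dose_time,
    dose_amount_mg,
    dose_is_oral,
    dose_duration,
    *,
    CL,
    V3,
    Q,
    V4,
    ka_fast,
    ka_slow,
    F_im_fast,
    F_oral,
    D_oral,
):
    """Vectorised closed-form concentration kernel (ng/mL).

    Shapes: ``times`` is (..., T); the four ``dose_*`` arrays are (..., D);
    every parameter must broadcast against (..., D), which permits per-dose
    parameters (e.g. occasion-specific clearance for IOV, per-subject
    F_im_fast).  Returns an array of shape (..., T).

    This is the workhorse behind :func:`concentration_closed_form` and the
    population simulation/estimation machinery; the dose loop is replaced
    by a broadcast axis so that whole cohorts evaluate in single numpy
    expressions.
    """
    times = np.asarray(times, dtype=float)
    dose_time = np.asarray(dose_time, dtype=float)
    dose_amount_mg = np.asarray(dose_amount_mg, dtype=float)
    dose_is_oral = np.asarray(dose_is_oral, dtype=bool)
    dose_duration = np.asarray(dose_duration, dtype=float)

    # park every parameter on the (..., D, 1) dose axis
    def dax(x):
        return np.asarray(x, dtype=float)[..., None] * np.ones_like(dose_time[..., None])

    CL, V3, Q, V4 = dax(CL), dax(V3), dax(Q), dax(V4)
    ka_f, ka_s = dax(ka_fast), dax(ka_slow)
    F_fast, F_or, D_or = dax(F_im_fast), dax(F_oral), dax(D_oral)

    k10 = CL / V3
    k12 = Q / V3
    k21 = Q / V4
    ssum = k10 + k12 + k21
    disc = np.sqrt(np.maximum(ssum * ssum - 4.0 * k10 * k21, 0.0))
    lam1 = 0.5 * (ssum + disc)
    lam2 = np.where(lam1 > 0, k10 * k21 / np.where(lam1 > 0, lam1, 1.0), 0.0)
    if np.any(lam2 <= 0):
        raise ValueError("degenerate disposition (lambda2 = 0); closed form undefined")

    dt = times[..., None, :] - dose_time[..., :, None]  # (..., D, T)
    active = dt >= 0.0
    dt = np.where(active, dt, 0.0)

    amt_ug = dose_amount_mg[..., :, None] * MG_TO_UG
    oral = dose_is_oral[..., :, None]
    e1 = np.exp(-lam1 * dt)
    e2 = np.exp(-lam2 * dt)

    out = np.zeros(np.broadcast_shapes(dt.shape, e1.shape), dtype=float)

    # --- IM: tri-exponential response to a first-order depot ---------------
    def depot(ka, frac):
        c1 = (k21 - lam1) / ((ka - lam1) * (lam2 - lam1))
        c2 = (k21 - lam2) / ((ka - lam2) * (lam1 - lam2))
        c3 = (k21 - ka) / ((lam1 - ka) * (lam2 - ka))
        unit = c1 * e1 + c2 * e2 + c3 * np.exp(-ka * dt)
        return (amt_ug * frac * ka / V3) * unit

    im_mask = ~oral & active
    if np.any(im_mask):
        contrib = depot(ka_f, F_fast) + depot(ka_s, 1.0 - F_fast)
        out += np.where(im_mask, contrib, 0.0)

    # --- oral: zero-order input into central, bi-exponential step ----------
    if np.any(oral):
        dur = np.where(
            dose_duration[..., :, None] > 0, dose_duration[..., :, None], D_or
        )
        rate = amt_ug * F_or / dur  # µg/h
        b1 = (k21 - lam1) / (lam1 * (lam2 - lam1))
        b2 = (k21 - lam2) / (lam2 * (lam1 - lam2))

        def step(tau):
            tau = np.maximum(tau, 0.0)
            return b1 * (1.0 - np.exp(-lam1 * tau)) + b2 * (1.0 - np.exp(-lam2 * tau))

        contrib = (rate / V3) * (step(dt) - step(dt - dur))
        out += np.where(oral & active, contrib, 0.0)

    return out.sum(axis=-2)


def _regimen_arrays(regimen: list[DoseEvent]):
    if any(regimen[i].time > regimen[i + 1].time for i in range(len(regimen) - 1)):
        raise ValueError("regimen must be sorted by time")
    t = np.array([d.time for d in regimen], dtype=float)
    a = np.array([d.amount for d in regimen], dtype=float)
    oral = np.array([d.route == ROUTE_ORAL for d in regimen], dtype=bool)
    dur = np.array([d.duration for d in regimen], dtype=float)
    occ = np.array([d.occasion for d in regimen], dtype=int)
    return t, a, oral, dur, occ


def concentration_closed_form(
    regimen: list[DoseEvent], params: PKParameters, times
) -> np.ndarray:
    """Concentration–time profile (ng/mL) by closed-form superposition.

    Times before the first dose return 0.  The regimen must be sorted by
    time; simultaneous doses superpose.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if len(regimen) == 0:
        return np.zeros_like(times)
    t, a, oral, dur, _ = _regimen_arrays(regimen)
    return superpose_profile(
        times, t, a, oral, dur,
        CL=params.CL, V3=params.V3, Q=params.Q, V4=params.V4,
        ka_fast=params.ka_fast, ka_slow=params.ka_slow,
        F_im_fast=params.F_im_fast, F_oral=params.F_oral, D_oral=params.D_oral,
    )


# ---------------------------------------------------------------------------
# ODE oracle
# ---------------------------------------------------------------------------

def concentration_ode(
    regimen: list[DoseEvent],
    params: PKParameters,
    times,
    rtol: float = 1e-10,
    atol: float = 1e-8,
    full_output: bool = False,
):
    """Numerical solution of the 4-state depot/disposition ODE system.

    States: fast depot, slow depot, central, peripheral (µg), plus a
    cumulative-elimination bookkeeping state.  Oral zero-order input enters
    the central compartment as a piecewise-constant source; IM doses are
    instantaneous additions to the two depots.  Integration proceeds
    segment-by-segment between input discontinuities so the stiff solver
    never steps across a jump.

    Serves as the independent oracle for :func:`concentration_closed_form`
    (agreement to <0.1% relative is part of the model contract).
    """
    if rtol <= 0 or atol <= 0:
        raise ValueError("solver tolerances must be positive")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    order = np.argsort(times, kind="stable")
    ts = times[order]
    conc = np.zeros_like(ts)
    if len(regimen) == 0:
        if full_output:
            return conc, {"states": np.zeros((len(ts), 5)), "administered": np.zeros(len(ts))}
        return conc

    t_dose, amt, oral, dur, _ = _regimen_arrays(regimen)
    dur = np.where(oral & (dur <= 0), params.D_oral, dur)

    # discontinuities of the input function
    breaks = np.unique(np.concatenate([t_dose, (t_dose + dur)[oral]]))
    t_end = max(float(ts.max()), float(breaks.max())) + 1.0
    breaks = np.append(breaks, t_end)

    d = disposition_constants(params)
    ka_f, ka_s = params.ka_fast, params.ka_slow

    def rhs(t, y, oral_rate):
        af, as_, a1, a2, _el = y
        return [
            -ka_f * af,
            -ka_s * as_,
            ka_f * af + ka_s * as_ + d.k21 * a2 - (d.k10 + d.k12) * a1 + oral_rate,
            d.k12 * a1 - d.k21 * a2,
            d.k10 * a1,
        ]

    y = np.zeros(5)
    states = np.zeros((len(ts), 5))
    administered = np.zeros(len(ts))
    cum_in = 0.0
    conc[ts < breaks[0]] = 0.0

    for i in range(len(breaks) - 1):
        t0, t1 = breaks[i], breaks[i + 1]
        # bolus depot deposits and start of oral infusions at t0
        here = t_dose == t0
        for j in np.where(here)[0]:
            a_ug = amt[j] * MG_TO_UG
            if oral[j]:
                continue  # handled through the rate term below
            y[0] += a_ug * params.F_im_fast
            y[1] += a_ug * (1.0 - params.F_im_fast)
            cum_in += a_ug
        # total oral input rate active on [t0, t1)
        infusing = oral & (t_dose <= t0) & (t_dose + dur > t0)
        rate = float(np.sum(amt[infusing] * MG_TO_UG * params.F_oral / dur[infusing]))

        sel = (ts >= t0) & (ts < t1)
        t_eval = ts[sel]
        if len(t_eval) > 0 or t1 > t0:
            sol = solve_ivp(
                rhs, (t0, t1), y, args=(rate,), method="LSODA",
                rtol=rtol, atol=atol, dense_output=True,
            )
            if not sol.success:
                raise RuntimeError(f"ODE integration failed on [{t0}, {t1}]: {sol.message}")
            if len(t_eval) > 0:
                seg = sol.sol(t_eval)
                conc[sel] = seg[2] / params.V3
                states[sel] = seg.T
                administered[sel] = cum_in + rate * (t_eval - t0)
            cum_in += rate * (t1 - t0)
            y = sol.y[:, -1]

    out = np.empty_like(conc)
    out[order] = conc
    if full_output:
        st = np.empty_like(states)
        st[order] = states
        adm = np.empty_like(administered)
        adm[order] = administered
        return out, {"states": st, "administered": adm}
    return out
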