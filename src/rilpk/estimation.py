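"""Approximate-likelihood estimation for the hierarchical PK model.

The marginal likelihood of each subject's data, integrated over that
subject's random effects, is approximated by the Laplace method: the inner
(empirical-Bayes) problem is solved per subject by a damped Gauss-Newton
iteration, and the curvature at the mode is evaluated by central finite
differences.  The objective function value (OFV) is −2 × the approximate
marginal log-likelihood summed over subjects, which makes nested models
comparable through chi-square ΔOFV tests exactly as in standard popPK
model building (3.84 for one parameter at α = 0.05 forward, 6.63 at
α = 0.01 backward).

All subjects are evaluated simultaneously: the inner Newton iteration, the
finite-difference Jacobians and the Laplace curvature are batched over the
cohort with numpy, which is what makes repeated fitting (bootstrap,
stepwise search, cross-validation, recovery studies) tractable.

Estimation is a deterministic gradient-based maximisation on transformed
scales (log for positive parameters and variance components, logit for the
fast-pathway fraction).  This estimator is of the first-order-conditional
family rather than stochastic EM; OFV values are internally consistent but
not comparable with other software's numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .params import PKParameters, RandomEffectsSpec, CovariateModel
from .pk_core import superpose_profile
from .dataset import ObservationTable

__all__ = [
    "FitResult",
    "CovariateEffect",
    "CovariateStepLog",
    "BootstrapResult",
    "ofv",
    "fit",
    "delta_ofv_test",
    "stepwise_covariates",
    "standard_candidates",
    "shrinkage",
    "bootstrap",
    "LaplaceObjective",
]

_LOG2PI = math.log(2.0 * math.pi)
_BSV_ORDER = ("F_oral", "ka_slow", "CL", "Ffast")  # canonical eta column order
_OMEGA_OF = {
    "F_oral": "omega_F_oral",
    "ka_slow": "omega_ka_slow",
    "CL": "omega_CL",
    "Ffast": "omega_eta_Ffast",
}
_POSITIVE_NAMES = {
    "CL", "V3", "Q", "V4", "ka_fast", "ka_slow", "F_oral", "D_oral",
    "omega_F_oral", "omega_ka_slow", "omega_CL", "omega_eta_Ffast",
    "omega_IOV_CL", "sigma_add_oral", "sigma_prop_im",
}
_VARIANCE_FLOOR = 1e-12


class EstimationError(RuntimeError):
    pass


class _GuardError(ValueError):
    """Parameter combination outside the admissible region."""


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate–parameter relation.

    kinds: 'sex_logit' multiplies the typical F_im_fast by (1 + beta·x)
    inside the logit (x = 1 for females); 'linear' multiplies the typical
    parameter by (1 + beta·(x − ref)); 'allometric' multiplies by
    (x/ref)**beta.
    """

    parameter: str
    covariate: str
    kind: str = "linear"
    ref: float = 0.0

    @property
    def name(self) -> str:
        return f"beta_{self.covariate}_{self.parameter}"


# ---------------------------------------------------------------------------
# Vectorised Laplace objective
# ---------------------------------------------------------------------------

class LaplaceObjective:
    """Batched −2·log marginal likelihood for one cohort.

    Holds padded (subject × dose) and (subject × observation) arrays built
    once from an :class:`ObservationTable`; every evaluation is then a
    handful of broadcast numpy expressions over the whole cohort.
    """

    def __init__(
        self,
        table: ObservationTable,
        eta_names: tuple[str, ...],
        iov: bool,
        covariate_effects: tuple[CovariateEffect, ...] = (),
    ):
        subs = table.subjects()
        if not subs:
            raise EstimationError("empty dataset")
        for s in subs:
            if not np.any(~s.obs_blq):
                raise EstimationError(
                    f"subject {s.id} has no usable (non-censored) observation"
                )
        S = len(subs)
        D = max(len(s.doses) for s in subs)
        usable = [~s.obs_blq for s in subs]
        T = max(int(u.sum()) for u in usable)

        self.subject_ids = np.array([s.id for s in subs])
        # dose blocks split by route: the closed-form kernel then evaluates
        # only the relevant input type per block (≈2× cheaper per call)
        Do = max(sum(d.route == "oral" for d in s.doses) for s in subs)
        Di = max(sum(d.route == "im" for d in s.doses) for s in subs)
        self.oral_time = np.zeros((S, Do))
        self.oral_amt = np.zeros((S, Do))
        self.oral_dur = np.zeros((S, Do))
        self.im_time = np.zeros((S, Di))
        self.im_amt = np.zeros((S, Di))
        self.im_occ = np.zeros((S, Di), dtype=int)
        self.dose_time = np.zeros((S, D))
        self.dose_amt = np.zeros((S, D))
        self.dose_oral = np.ones((S, D), dtype=bool)  # zero-amount oral padding
        self.dose_dur = np.zeros((S, D))
        self.dose_occ = np.zeros((S, D), dtype=int)
        self.obs_time = np.zeros((S, T))
        self.obs_dv = np.zeros((S, T))
        self.obs_oral = np.ones((S, T), dtype=bool)
        self.obs_mask = np.zeros((S, T), dtype=bool)
        self.female = np.array([float(s.female) for s in subs])
        self.covariates = {
            "SEX": self.female,
            "AGE": np.array([s.age for s in subs]),
            "WT": np.array([s.weight for s in subs]),
            "BMI": np.array([s.bmi for s in subs]),
        }
        for i, s in enumerate(subs):
            nd = len(s.doses)
            self.dose_time[i, :nd] = [d.time for d in s.doses]
            self.dose_amt[i, :nd] = [d.amount for d in s.doses]
            self.dose_oral[i, :nd] = [d.route == "oral" for d in s.doses]
            self.dose_dur[i, :nd] = [d.duration for d in s.doses]
            self.dose_occ[i, :nd] = [d.occasion for d in s.doses]
            orals = [d for d in s.doses if d.route == "oral"]
            ims = [d for d in s.doses if d.route == "im"]
            self.oral_time[i, :len(orals)] = [d.time for d in orals]
            self.oral_amt[i, :len(orals)] = [d.amount for d in orals]
            self.oral_dur[i, :len(orals)] = [d.duration for d in orals]
            self.im_time[i, :len(ims)] = [d.time for d in ims]
            self.im_amt[i, :len(ims)] = [d.amount for d in ims]
            self.im_occ[i, :len(ims)] = [d.occasion for d in ims]
            u = usable[i]
            k = int(u.sum())
            self.obs_time[i, :k] = s.obs_time[u]
            self.obs_dv[i, :k] = s.obs_dv[u]
            self.obs_oral[i, :k] = s.obs_route_oral[u]
            self.obs_mask[i, :k] = True

        self.n_subjects = S
        self.n_obs = int(self.obs_mask.sum())
        self.eta_names = tuple(eta_names)
        self.iov = bool(iov)
        self.n_occ = int(self.dose_occ.max()) if iov else 0
        self.q = len(self.eta_names) + self.n_occ
        self.effects = tuple(covariate_effects)
        self._warm = np.zeros((S, self.q))

    # -- model mapping -----------------------------------------------------

    def _subject_params(self, md: dict, eta: np.ndarray):
        """Per-subject / per-dose parameter arrays from the model dict and
        the (S, q) random-effect matrix."""
        S = self.n_subjects
        idx = {n: j for j, n in enumerate(self.eta_names)}

        def eta_col(name):
            return eta[:, idx[name]] if name in idx else np.zeros(S)

        # covariate multipliers
        theta_ffast = np.full(S, md["F_im_fast"])
        cl_factor = np.ones(S)
        for eff in self.effects:
            beta = md[eff.name]
            x = self.covariates[eff.covariate]
            if eff.kind == "sex_logit":
                fac = 1.0 + beta * x
            elif eff.kind == "linear":
                fac = 1.0 + beta * (x - eff.ref)
            elif eff.kind == "allometric":
                fac = (x / eff.ref) ** beta
            else:
                raise ValueError(f"unknown covariate kind {eff.kind!r}")
            if eff.parameter == "F_im_fast":
                theta_ffast = theta_ffast * fac
            elif eff.parameter == "CL":
                cl_factor = cl_factor * fac
            else:
                raise ValueError(f"covariates not supported on {eff.parameter!r}")
        if np.any(theta_ffast <= 0.0) or np.any(theta_ffast >= 1.0) or np.any(cl_factor <= 0.0):
            raise _GuardError("covariate-adjusted parameter outside its domain")

        temp = np.log(theta_ffast / (1.0 - theta_ffast))
        f_fast = 1.0 / (1.0 + np.exp(-(temp + eta_col("Ffast"))))

        kap_im = np.zeros_like(self.im_time)
        if self.iov and self.n_occ > 0:
            kappa = eta[:, len(self.eta_names):]  # (S, n_occ)
            occ = self.im_occ
            has = occ > 0
            kap_im[has] = kappa[np.nonzero(has)[0], occ[has] - 1]
        cl_s = md["CL"] * cl_factor * np.exp(eta_col("CL"))

        return {
            "CL_s": cl_s[:, None],
            "CL_im": cl_s[:, None] * np.exp(kap_im),
            "ka_slow_s": (md["ka_slow"] * np.exp(eta_col("ka_slow")))[:, None],
            "F_oral_s": (md["F_oral"] * np.exp(eta_col("F_oral")))[:, None],
            "F_fast_s": f_fast[:, None],
        }

    def predict(self, md: dict, eta: np.ndarray) -> np.ndarray:
        p = self._subject_params(md, eta)
        shared = dict(V3=md["V3"], Q=md["Q"], V4=md["V4"], ka_fast=md["ka_fast"],
                      ka_slow=p["ka_slow_s"], F_im_fast=p["F_fast_s"],
                      F_oral=p["F_oral_s"], D_oral=md["D_oral"])
        out = superpose_profile(
            self.obs_time, self.oral_time, self.oral_amt,
            np.ones_like(self.oral_amt, dtype=bool), self.oral_dur,
            CL=p["CL_s"], **shared,
        )
        if self.im_time.shape[1]:
            out = out + superpose_profile(
                self.obs_time, self.im_time, self.im_amt,
                np.zeros_like(self.im_amt, dtype=bool),
                np.zeros_like(self.im_amt),
                CL=p["CL_im"], **shared,
            )
        return out

    def _omega_vector(self, md: dict) -> np.ndarray:
        om = [md[_OMEGA_OF[n]] for n in self.eta_names]
        om += [md["omega_IOV_CL"]] * self.n_occ
        om = np.asarray(om, dtype=float)
        if np.any(om <= 0):
            raise _GuardError("active random-effect SD must be > 0")
        return om

    def _data_terms(self, md, pred):
        r = self.obs_dv - pred
        v = np.where(
            self.obs_oral,
            md["sigma_add_oral"] ** 2,
            (md["sigma_prop_im"] * pred) ** 2,
        )
        v = np.maximum(v, _VARIANCE_FLOOR)
        return r, v

    def g(self, md: dict, eta: np.ndarray) -> np.ndarray:
        """Per-subject −log joint density (data + random-effect prior)."""
        pred = self.predict(md, eta)
        r, v = self._data_terms(md, pred)
        ll = 0.5 * np.where(self.obs_mask, r * r / v + np.log(2.0 * math.pi * v), 0.0).sum(axis=1)
        if self.q:
            om = self._omega_vector(md)
            ll = ll + 0.5 * ((eta / om) ** 2).sum(axis=1) + 0.5 * np.sum(
                np.log(2.0 * math.pi * om ** 2)
            )
        if not np.all(np.isfinite(ll)):
            bad = self.subject_ids[~np.isfinite(ll)]
            raise EstimationError(f"non-finite likelihood for subject(s) {bad.tolist()}")
        return ll

    # -- inner (empirical-Bayes) problem ------------------------------------

    def _gauss_newton_parts(self, md, eta, om):
        """Gradient of g and its Gauss-Newton curvature at eta (batched)."""
        S, q = self.n_subjects, self.q
        pred0 = self.predict(md, eta)
        r, v = self._data_terms(md, pred0)
        h = 1e-5 * (1.0 + np.abs(eta))
        J = np.empty((S, self.obs_mask.shape[1], q))
        for j in range(q):
            ej = eta.copy()
            ej[:, j] += h[:, j]
            J[:, :, j] = (self.predict(md, ej) - pred0) / h[:, j][:, None]
        dvdp = np.where(self.obs_oral, 0.0, 2.0 * md["sigma_prop_im"] ** 2 * pred0)
        w_r = np.where(self.obs_mask, -r / v, 0.0)
        w_v = np.where(self.obs_mask, 0.5 * (1.0 / v - (r * r) / (v * v)) * dvdp, 0.0)
        grad = np.einsum("st,stq->sq", w_r + w_v, J) + eta / om ** 2
        # curvature weight = exact d²/dp² of the per-observation −log density
        # (for proportional error the variance depends on the prediction, and
        # without these terms the Newton iteration degrades to a slow linear
        # rate); second derivatives of the prediction itself are dropped.
        c = md["sigma_prop_im"] ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            p2 = np.maximum(pred0, 1e-6) ** 2
            p3 = p2 * np.maximum(pred0, 1e-6)
            p4 = p2 * p2
            w_im = (1.0 / c - 1.0) / p2 + 4.0 * r / (c * p3) + 3.0 * r * r / (c * p4)
        W = np.where(self.obs_oral, 1.0 / v, w_im)
        W = np.where(self.obs_mask, np.maximum(W, 0.0), 0.0)
        H = np.einsum("st,stq,stp->sqp", W, J, J)
        H[:, np.arange(q), np.arange(q)] += 1.0 / om ** 2
        return grad, H

    def solve_inner(self, md, eta0=None, tol=1e-6, max_iter=40):
        """Batched damped Gauss-Newton minimisation of g over eta."""
        S, q = self.n_subjects, self.q
        if q == 0:
            return np.zeros((S, 0))
        eta = np.array(eta0 if eta0 is not None else self._warm, dtype=float)
        om = self._omega_vector(md)
        lam = np.full(S, 1e-3)
        g_cur = self.g(md, eta)
        for _ in range(max_iter):
            grad, H = self._gauss_newton_parts(md, eta, om)
            gnorm = np.abs(grad).max(axis=1)
            active = gnorm > tol * (1.0 + np.abs(g_cur))
            if not active.any():
                break
            g_before = g_cur.copy()
            pending = active.copy()
            for _try in range(8):
                Hd = H.copy()
                Hd[:, np.arange(q), np.arange(q)] *= (1.0 + lam)[:, None]
                try:
                    step = np.linalg.solve(Hd, -grad[..., None])[..., 0]
                except np.linalg.LinAlgError:
                    Hd[:, np.arange(q), np.arange(q)] += 1e-8
                    step = np.linalg.solve(Hd, -grad[..., None])[..., 0]
                # random effects live on log/logit scales: steps beyond a few
                # units are pathological and can underflow the disposition
                step = np.clip(step, -3.0, 3.0)
                trial = np.where(pending[:, None], np.clip(eta + step, -30.0, 30.0), eta)
                g_new = self.g(md, trial)
                better = pending & (g_new <= g_cur + 1e-12)
                eta[better] = trial[better]
                g_cur = np.where(better, g_new, g_cur)
                lam = np.where(better, np.maximum(lam * 0.3, 1e-8), lam)
                pending = pending & ~better
                if not pending.any():
                    break
                lam = np.where(pending, lam * 10.0, lam)
            # FD-gradient noise sets a floor on attainable gnorm; stop once
            # the objective no longer moves
            if np.max(g_before - g_cur) < 1e-10 * (1.0 + np.abs(g_cur).max()):
                break
        return eta

    def _hessian_g(self, md, eta):
        """Exact (central finite-difference) Hessian of g at eta, (S,q,q)."""
        S, q = self.n_subjects, self.q
        h = 1e-4 * (1.0 + np.abs(eta))
        H = np.zeros((S, q, q))

        def gp(delta):
            return self.g(md, eta + delta)

        g0 = self.g(md, eta)
        for i in range(q):
            ei = np.zeros_like(eta)
            ei[:, i] = h[:, i]
            H[:, i, i] = (gp(ei) - 2.0 * g0 + gp(-ei)) / h[:, i] ** 2
            for j in range(i + 1, q):
                ej = np.zeros_like(eta)
                ej[:, j] = h[:, j]
                val = (gp(ei + ej) - gp(ei - ej) - gp(-ei + ej) + gp(-ei - ej)) / (
                    4.0 * h[:, i] * h[:, j]
                )
                H[:, i, j] = H[:, j, i] = val
        return H

    def value(self, md: dict, curvature: str = "gn") -> float:
        """Laplace OFV = −2·log marginal likelihood of the whole cohort.

        ``curvature`` selects the mode curvature entering the Laplace
        determinant: 'gn' (default) uses the Gauss-Newton approximation —
        the first-order-conditional convention, cheap and positive
        definite by construction; 'exact' uses central finite differences
        of g (falling back to Gauss-Newton where that is not positive
        definite).
        """
        if self.q == 0:
            return float(2.0 * self.g(md, np.zeros((self.n_subjects, 0))).sum())
        eta_hat = self.solve_inner(md)
        self._warm = eta_hat
        g_hat = self.g(md, eta_hat)
        om = self._omega_vector(md)
        _grad, Hgn = self._gauss_newton_parts(md, eta_hat, om)
        if curvature == "gn":
            H = Hgn
        else:
            H = self._hessian_g(md, eta_hat)
            sign, _ = np.linalg.slogdet(H)
            H[sign <= 0] = Hgn[sign <= 0]
        sign, logdet = np.linalg.slogdet(H)
        if np.any(sign <= 0):
            bad = self.subject_ids[sign <= 0]
            raise EstimationError(
                f"non-positive Laplace curvature for subject(s) {bad.tolist()}"
            )
        return float((2.0 * g_hat - self.q * _LOG2PI + logdet).sum())


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def _model_dict(params: PKParameters, re_spec: RandomEffectsSpec, betas: dict) -> dict:
    md = params.as_dict()
    md.update(re_spec.as_dict())
    md.update(betas)
    return md


def _active_dims(re_spec: RandomEffectsSpec, estimate=()):
    names = tuple(
        n for n in _BSV_ORDER
        if getattr(re_spec, _OMEGA_OF[n]) > 0 or _OMEGA_OF[n] in estimate
    )
    iov = re_spec.omega_IOV_CL > 0 or "omega_IOV_CL" in estimate
    return names, iov


def _effects_from_model(covariate_model: CovariateModel | None):
    if covariate_model is None or covariate_model.theta_female == 0.0:
        return (), {}
    eff = CovariateEffect(parameter="F_im_fast", covariate="SEX", kind="sex_logit")
    return (eff,), {eff.name: covariate_model.theta_female}


def ofv(
    table: ObservationTable,
    params: PKParameters,
    re_spec: RandomEffectsSpec,
    covariate_model: CovariateModel | None = None,
    curvature: str = "gn",
) -> float:
    """Laplace OFV of a parameter set on a dataset (no fitting).

    With all random-effect SDs at zero this reduces exactly to
    −2·Σ log φ(residuals) under the fixed-effect model.
    """
    effects, betas = _effects_from_model(covariate_model)
    names, iov = _active_dims(re_spec)
    obj = LaplaceObjective(table, names, iov, effects)
    return obj.value(_model_dict(params, re_spec, betas), curvature=curvature)


@dataclass
class FitResult:
    params: PKParameters
    re_spec: RandomEffectsSpec
    betas: dict
    ofv: float
    estimates: dict
    se: dict
    rse_percent: dict
    eta: np.ndarray
    eta_names: tuple
    subject_ids: np.ndarray
    converged: bool
    message: str
    n_obs: int
    fixed: tuple

    def eb_effects(self, name: str) -> np.ndarray:
        """Empirical-Bayes estimates of one BSV dimension across subjects."""
        return self.eta[:, self.eta_names.index(name)]

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, val in self.estimates.items():
            rows.append(dict(
                parameter=name, estimate=val,
                se=self.se.get(name, np.nan),
                rse_percent=self.rse_percent.get(name, np.nan),
            ))
        return pd.DataFrame(rows)


_DEFAULT_ESTIMATE = (
    "CL", "V3", "Q", "V4", "ka_fast", "ka_slow", "F_im_fast", "F_oral",
    "omega_F_oral", "omega_ka_slow", "omega_CL", "omega_eta_Ffast",
    "omega_IOV_CL", "sigma_add_oral", "sigma_prop_im",
)


def _transform(name, value):
    if name in _POSITIVE_NAMES:
        return math.log(value)
    if name == "F_im_fast":
        return math.log(value / (1.0 - value))
    return value  # covariate betas: identity


def _back_transform(name, z):
    if name in _POSITIVE_NAMES:
        return math.exp(z)
    if name == "F_im_fast":
        return 1.0 / (1.0 + math.exp(-z))
    return z


def _dnat_dtrans(name, value):
    if name in _POSITIVE_NAMES:
        return value
    if name == "F_im_fast":
        return value * (1.0 - value)
    return 1.0


def fit(
    table: ObservationTable,
    init: PKParameters,
    init_re: RandomEffectsSpec,
    estimate: tuple = _DEFAULT_ESTIMATE,
    covariate_effects: tuple = (),
    init_betas: dict | None = None,
    compute_se: bool = True,
    maxiter: int = 300,
    warn_small: bool = True,
) -> FitResult:
    """Maximum (Laplace-approximate) likelihood fit.

    ``estimate`` names the free parameters; anything not listed is held at
    its initial value (D_oral is fixed by default, matching the model
    definition).  Positive parameters and variance components are
    optimised on the log scale, F_im_fast on the logit scale, covariate
    coefficients untransformed.  Standard errors come from the
    finite-difference curvature of the OFV at the optimum
    (RSE% = 100·SE/estimate on the natural scale).
    """
    if warn_small and table.n_subjects < 3:
        import warnings

        warnings.warn("fewer than 3 subjects: the design is unlikely to be identifiable")
    init_betas = dict(init_betas or {})
    for eff in covariate_effects:
        init_betas.setdefault(eff.name, 0.0)
    unknown = [n for n in estimate
               if n not in _POSITIVE_NAMES | {"F_im_fast"} | set(init_betas)]
    if unknown:
        raise ValueError(f"cannot estimate unknown parameter(s): {unknown}")

    names, iov = _active_dims(init_re, estimate)
    obj = LaplaceObjective(table, names, iov, tuple(covariate_effects))
    base_md = _model_dict(init, init_re, init_betas)

    free = [n for n in estimate]
    x0 = np.array([_transform(n, base_md[n]) for n in free])
    bounds = []
    for n, z in zip(free, x0):
        if n.startswith("omega_") or n.startswith("sigma_"):
            bounds.append((math.log(1e-3), math.log(5.0) if n.startswith("omega_") else math.log(1e3)))
        elif n == "F_im_fast":
            bounds.append((-6.0, 6.0))
        elif n in _POSITIVE_NAMES:
            bounds.append((z - math.log(50.0), z + math.log(50.0)))
        else:  # covariate beta
            bounds.append((-0.95, 10.0))

    def objective(x):
        md = dict(base_md)
        for n, z in zip(free, x):
            md[n] = _back_transform(n, z)
        try:
            return obj.value(md)
        except (_GuardError, EstimationError, FloatingPointError):
            return 1e12

    if len(free) == 0:  # evaluation-only "fit": empirical-Bayes pass
        from types import SimpleNamespace

        res = SimpleNamespace(x=x0, fun=objective(x0), success=True,
                              message="no free parameters")
    else:
        opts = {"maxiter": maxiter, "eps": 1e-5, "ftol": 1e-11, "gtol": 1e-4}
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds, options=opts)
        # restart from the optimum until the OFV stops improving: a restart
        # resets the quasi-Newton memory, which recovers from premature
        # line-search termination on a noisy FD gradient
        for _round in range(2):
            res2 = minimize(objective, res.x, method="L-BFGS-B", bounds=bounds,
                            options=opts)
            improved = res.fun - res2.fun
            if res2.fun <= res.fun:
                res = res2
            if improved < 0.01:
                break
    x_opt = res.x
    estimates = {n: _back_transform(n, z) for n, z in zip(free, x_opt)}
    md_opt = dict(base_md)
    md_opt.update(estimates)

    se, rse = {}, {}
    if compute_se and len(free) > 0:
        # step large enough that OFV differences dominate inner-solver noise
        Ht = _fd_hessian(objective, x_opt, rel_step=1e-2)
        cov = None
        try:
            cov = 2.0 * np.linalg.inv(Ht)
        except np.linalg.LinAlgError:
            pass
        if cov is not None:
            d = np.sqrt(np.maximum(np.diag(cov), 0.0))
            for i, n in enumerate(free):
                se[n] = d[i] * abs(_dnat_dtrans(n, estimates[n]))
                rse[n] = 100.0 * se[n] / abs(estimates[n]) if estimates[n] != 0 else np.inf

    final_ofv = obj.value(md_opt)  # refresh warm etas at the optimum
    eta_hat = obj.solve_inner(md_opt) if obj.q else np.zeros((obj.n_subjects, 0))

    pk_fields = set(PKParameters.__dataclass_fields__)
    re_fields = set(RandomEffectsSpec.__dataclass_fields__)
    params_out = init.with_(**{k: v for k, v in estimates.items() if k in pk_fields})
    re_out = init_re.with_(**{k: v for k, v in estimates.items() if k in re_fields})
    betas_out = dict(init_betas)
    betas_out.update({k: v for k, v in estimates.items() if k in init_betas})

    return FitResult(
        params=params_out, re_spec=re_out, betas=betas_out,
        ofv=float(final_ofv), estimates=estimates, se=se, rse_percent=rse,
        eta=eta_hat, eta_names=obj.eta_names, subject_ids=obj.subject_ids,
        converged=bool(res.success), message=str(res.message), n_obs=obj.n_obs,
        fixed=tuple(n for n in base_md if n not in estimates),
    )


def _fd_hessian(f, x, rel_step=1e-4):
    n = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.zeros((n, n))
    f0 = f(x)

    def fp(delta):
        return f(x + delta)

    for i in range(n):
        ei = np.zeros(n)
        ei[i] = h[i]
        H[i, i] = (fp(ei) - 2.0 * f0 + fp(-ei)) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fp(ei + ej) - fp(ei - ej) - fp(-ei + ej) + fp(-ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def delta_ofv_test(ofv_reduced: float, ofv_full: float, df: int = 1, alpha: float = 0.05):
    """Likelihood-ratio decision for nested models.

    Returns (significant, delta_ofv, threshold): the richer model wins when
    ΔOFV = OFV_full − OFV_reduced < −χ²(1−α, df); at df=1 the thresholds
    are 3.84 (α=0.05) and 6.63 (α=0.01).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    threshold = float(chi2.ppf(1.0 - alpha, df))
    delta = ofv_full - ofv_reduced
    return bool(delta < -threshold), float(delta), threshold


@dataclass
class CovariateStepLog:
    forward: list = field(default_factory=list)   # (candidate, delta_ofv, decision)
    backward: list = field(default_factory=list)
    final_effects: tuple = ()
    final_fit: FitResult | None = None
    base_fit: FitResult | None = None


def standard_candidates(table: ObservationTable, target: str = "F_im_fast") -> dict:
    """Default candidate set: sex (multiplicative inside the logit) plus
    linear age, body weight and BMI, centred at the cohort median."""
    cov = table.covariate_frame()
    out = {"sex": CovariateEffect(target, "SEX", "sex_logit")}
    for name, col in (("age", "AGE"), ("weight", "WT"), ("bmi", "BMI")):
        out[name] = CovariateEffect(target, col, "linear", ref=float(cov[col].median()))
    return out


def stepwise_covariates(
    table: ObservationTable,
    init: PKParameters,
    init_re: RandomEffectsSpec,
    candidates: dict | None = None,
    estimate: tuple = _DEFAULT_ESTIMATE,
    alpha_forward: float = 0.05,
    alpha_backward: float = 0.01,
    maxiter: int = 300,
) -> CovariateStepLog:
    """Univariate forward scan + full-model backward deletion.

    Each candidate is added alone to the base model and kept for the full
    model when its ΔOFV beats the forward χ² threshold; the full model is
    then pruned by removing, one at a time, the effect whose deletion
    costs the least, until every remaining effect's removal would raise
    the OFV by more than the backward threshold.
    """
    if candidates is None:
        candidates = standard_candidates(table)
    log = CovariateStepLog()

    def _fit(effects, start=init, start_re=init_re):
        return fit(
            table, start, start_re,
            estimate=tuple(estimate) + tuple(e.name for e in effects),
            covariate_effects=tuple(effects), compute_se=False, maxiter=maxiter,
        )

    base = fit(table, init, init_re, estimate=tuple(estimate),
               compute_se=False, maxiter=maxiter)
    log.base_fit = base
    # candidate fits start from the base optimum (nested-model warm start)
    init, init_re = base.params, base.re_spec
    selected = []
    for name, eff in candidates.items():
        try:
            cand_fit = _fit((eff,))
        except EstimationError:
            log.forward.append((name, np.nan, "failed"))
            continue
        sig, delta, _ = delta_ofv_test(base.ofv, cand_fit.ofv, 1, alpha_forward)
        log.forward.append((name, delta, "added" if sig else "rejected"))
        if sig:
            selected.append((name, eff))

    current = list(selected)
    current_fit = _fit(tuple(e for _, e in current)) if current else base
    while current:
        drops = []
        for i, (name, _eff) in enumerate(current):
            reduced = [e for j, (_, e) in enumerate(current) if j != i]
            red_fit = _fit(tuple(reduced)) if reduced else base
            removal_delta = red_fit.ofv - current_fit.ofv
            drops.append((removal_delta, i, name, red_fit))
        removal_delta, i, name, red_fit = min(drops)
        threshold = float(chi2.ppf(1.0 - alpha_backward, 1))
        if removal_delta < threshold:
            log.backward.append((name, removal_delta, "removed"))
            current.pop(i)
            current_fit = red_fit
        else:
            for rd, _i, nm, _f in drops:
                log.backward.append((nm, rd, "retained"))
            break
    log.final_effects = tuple(e for _, e in current)
    log.final_fit = current_fit
    return log


def shrinkage(eb_effects: np.ndarray, omega: float) -> float:
    """Eta-shrinkage %: 100·(1 − SD(η̂)/ω).

    High shrinkage means the design carries little individual information
    and the empirical-Bayes effects collapse toward zero.
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    eb = np.asarray(eb_effects, dtype=float)
    return 100.0 * (1.0 - eb.std(ddof=1) / omega)


def stratified_resample(rng: np.random.Generator, ids: np.ndarray, female: np.ndarray) -> np.ndarray:
    """Resample subject ids with replacement within each sex stratum, so a
    replicate keeps the original female/male counts exactly."""
    f = rng.choice(ids[female], size=int(female.sum()), replace=True)
    m = rng.choice(ids[~female], size=int((~female).sum()), replace=True)
    return np.concatenate([f, m])


@dataclass
class BootstrapResult:
    estimates: pd.DataFrame      # one row per converged replicate
    median: dict
    ci95: dict                   # name -> (2.5th, 97.5th percentile)
    n_requested: int
    n_failed: int


def bootstrap(
    table: ObservationTable,
    init: PKParameters,
    init_re: RandomEffectsSpec,
    n_replicates: int = 200,
    seed: int = 0,
    estimate: tuple = _DEFAULT_ESTIMATE,
    stratify_sex: bool = True,
    identity: bool = False,
    maxiter: int = 300,
) -> BootstrapResult:
    """Subject-level nonparametric bootstrap of the fit.

    Subjects are resampled with replacement (stratified by sex so each
    replicate keeps the observed female count); each replicate is refit
    and non-converged replicates are dropped with a count.  ``identity``
    skips resampling (every replicate is the original cohort) — useful to
    verify the machinery reproduces the original fit.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    cov = table.covariate_frame()
    ids = cov["ID"].to_numpy()
    female = cov["SEX"].to_numpy().astype(bool)
    rows, n_failed = [], 0
    for _rep in range(n_replicates):
        if identity:
            chosen = ids
        elif stratify_sex:
            chosen = stratified_resample(rng, ids, female)
        else:
            chosen = rng.choice(ids, size=len(ids), replace=True)
        rep_table = table.resample(chosen)
        try:
            r = fit(rep_table, init, init_re, estimate=estimate,
                    compute_se=False, maxiter=maxiter, warn_small=False)
        except (EstimationError, _GuardError):
            n_failed += 1
            continue
        if not np.isfinite(r.ofv):
            n_failed += 1
            continue
        rows.append(r.estimates)
    if not rows:
        raise EstimationError("all bootstrap replicates failed")
    est = pd.DataFrame(rows)
    return BootstrapResult(
        estimates=est,
        median={c: float(est[c].median()) for c in est.columns},
        ci95={c: (float(est[c].quantile(0.025)), float(est[c].quantile(0.975)))
              for c in est.columns},
        n_requested=n_replicates,
        n_failed=n_failed,
    )
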