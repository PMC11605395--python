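"""Model qualification: prediction-corrected VPC and cross-validation.

The pcVPC compares observed percentiles with the model's simulated
percentile distributions after rescaling every record by the ratio of its
bin's median typical prediction to the record's own typical prediction —
this removes the spread caused by differing regimens and sampling times so
heterogeneous designs can share bins.  Cross-validation refits the model
on random 80% subject subsets and scores population predictions on the
held-out 20% with MPE and RMSE on log concentrations (×100, an
approximate percent scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import PKParameters, RandomEffectsSpec, CovariateModel
from .dataset import ObservationTable
from .estimation import (
    LaplaceObjective,
    EstimationError,
    _active_dims,
    _effects_from_model,
    _model_dict,
    fit as _fit,
)

__all__ = ["VpcResult", "XvalResult", "pcvpc", "cross_validate", "plot_vpc"]


@dataclass
class VpcResult:
    """Binned observed percentiles with simulated confidence bands.

    ``table`` has one row per (route, bin): bin edges and midpoint of
    time-since-last-dose, observed 5/50/95th percentiles of the
    prediction-corrected data, and the simulated 90% CI of each
    percentile.
    """

    table: pd.DataFrame
    n_sim: int
    merged_bins: int = 0

    def coverage(self) -> float:
        """Fraction of (bin × percentile) statistics whose observed value
        falls inside the simulated 90% CI — ≈0.9 for a correct model."""
        hits = 0
        total = 0
        for p in (5, 50, 95):
            obs = self.table[f"obs_p{p}"]
            lo = self.table[f"sim_p{p}_lo"]
            hi = self.table[f"sim_p{p}_hi"]
            hits += int(((obs >= lo) & (obs <= hi)).sum())
            total += len(obs)
        return hits / total if total else float("nan")


def _time_since_last_dose(obj: LaplaceObjective) -> np.ndarray:
    """(S, T) time from the most recent dose to each observation."""
    dt = obj.obs_time[:, None, :] - obj.dose_time[:, :, None]  # (S, D, T)
    real_dose = obj.dose_amt[:, :, None] > 0
    # strictly positive: a sample at exactly an injection time is a pre-dose
    # trough of the preceding interval
    dt = np.where((dt > 0) & real_dose, dt, np.inf)
    out = dt.min(axis=1)
    return np.where(np.isfinite(out), out, 0.0)


def pcvpc(
    table: ObservationTable,
    params: PKParameters,
    re_spec: RandomEffectsSpec,
    n_sim: int = 200,
    n_bins: int = 8,
    seed: int = 0,
    covariate_model: CovariateModel | None = None,
    lloq: float = 5.0,
) -> VpcResult:
    """Prediction-corrected visual predictive check.

    Simulates ``n_sim`` replicates of the dataset under the model (fresh
    random effects and residual noise on the observed design), bins
    records by time since last dose within each route, prediction-corrects
    both observed and simulated values by the bin-median typical
    prediction, and summarises the 5/50/95th percentiles.  Censored
    records are excluded from the observed data, and simulated values
    below ``lloq`` are dropped symmetrically so the percentile statistics
    stay comparable.  Bins that would be empty are merged
    into their neighbours by the equal-count edge construction.
    """
    effects, betas = _effects_from_model(covariate_model)
    names, iov = _active_dims(re_spec)
    obj = LaplaceObjective(table, names, iov, effects)
    md = _model_dict(params, re_spec, betas)
    S = obj.n_subjects

    pred_typ = obj.predict(md, np.zeros((S, obj.q)))
    mask = obj.obs_mask
    tsld = _time_since_last_dose(obj)

    flat = mask.ravel()
    route_oral = obj.obs_oral.ravel()[flat]
    x = tsld.ravel()[flat]
    dv = obj.obs_dv.ravel()[flat]
    pred = pred_typ.ravel()[flat]

    rng = np.random.default_rng(seed)
    om = [getattr(re_spec, n) for n in
          ("omega_F_oral", "omega_ka_slow", "omega_CL", "omega_eta_Ffast")]
    om_by_name = dict(zip(("F_oral", "ka_slow", "CL", "Ffast"), om))
    sims = np.empty((n_sim, flat.sum()))
    for r in range(n_sim):
        eta = np.zeros((S, obj.q))
        for j, n_ in enumerate(obj.eta_names):
            eta[:, j] = rng.normal(0.0, om_by_name[n_], S)
        if obj.iov and obj.n_occ:
            eta[:, len(obj.eta_names):] = rng.normal(
                0.0, re_spec.omega_IOV_CL, (S, obj.n_occ)
            )
        p = obj.predict(md, eta)
        noise_add = rng.normal(0.0, re_spec.sigma_add_oral, p.shape)
        noise_prop = rng.normal(0.0, re_spec.sigma_prop_im, p.shape)
        y = np.where(obj.obs_oral, p + noise_add, p * (1.0 + noise_prop))
        y = np.where(y < lloq, np.nan, y)  # mirror the BLQ exclusion
        sims[r] = y.ravel()[flat]

    rows = []
    merged = 0
    for oral_flag, route in ((True, "oral"), (False, "im")):
        sel = route_oral == oral_flag
        if not sel.any():
            continue
        xs = x[sel]
        k = min(n_bins, max(1, len(np.unique(xs))))
        edges = np.unique(np.quantile(xs, np.linspace(0, 1, k + 1)))
        merged += (k + 1) - len(edges)
        if len(edges) == 1:  # all records share one time-since-dose
            edges = np.repeat(edges, 2)
        which = np.clip(np.searchsorted(edges, xs, side="right") - 1, 0, len(edges) - 2)
        for b in range(len(edges) - 1):
            inbin = sel.copy()
            inbin[sel] = which == b
            if not inbin.any():
                continue
            corr = np.median(pred[inbin]) / pred[inbin]
            obs_pc = dv[inbin] * corr
            sim_pc = sims[:, inbin] * corr[None, :]
            row = dict(
                route=route, bin=b,
                t_lo=float(edges[b]), t_hi=float(edges[b + 1]),
                t_mid=float(np.median(x[inbin])), n=int(inbin.sum()),
            )
            for p_ in (5, 50, 95):
                row[f"obs_p{p_}"] = float(np.percentile(obs_pc, p_))
                stat = np.nanpercentile(sim_pc, p_, axis=1)
                row[f"sim_p{p_}_lo"] = float(np.percentile(stat, 5))
                row[f"sim_p{p_}_hi"] = float(np.percentile(stat, 95))
            rows.append(row)
    return VpcResult(table=pd.DataFrame(rows), n_sim=n_sim, merged_bins=merged)


def plot_vpc(result: VpcResult, axes=None):
    """Two-panel (oral | IM) pcVPC plot: observed percentile lines over the
    shaded simulated 90% CIs."""
    import matplotlib.pyplot as plt

    routes = [r for r in ("oral", "im") if (result.table["route"] == r).any()]
    if axes is None:
        _fig, axes = plt.subplots(1, max(len(routes), 1), figsize=(10, 4))
    axes = np.atleast_1d(axes)
    for ax, route in zip(axes, routes):
        sub = result.table[result.table["route"] == route]
        t = sub["t_mid"] / 24.0
        for p, style in ((5, "--"), (50, "-"), (95, "--")):
            ax.fill_between(t, sub[f"sim_p{p}_lo"], sub[f"sim_p{p}_hi"],
                            alpha=0.3, color="tab:blue" if p == 50 else "tab:gray")
            ax.plot(t, sub[f"obs_p{p}"], style, color="k", lw=1.2)
        ax.set_title(route)
        ax.set_xlabel("time since last dose (days)")
        ax.set_ylabel("prediction-corrected concentration (ng/mL)")
    return axes


@dataclass
class XvalResult:
    splits: pd.DataFrame          # per-split MPE%, RMSE%, sizes
    mean_mpe: float
    mpe_ci95: tuple               # across splits (t-interval)
    mean_rmse: float
    skipped: int = 0


def cross_validate(
    table: ObservationTable,
    init: PKParameters,
    init_re: RandomEffectsSpec,
    k: int = 5,
    train_frac: float = 0.8,
    seed: int = 0,
    estimate: tuple | None = None,
    maxiter: int = 300,
) -> XvalResult:
    """Repeated random data-splitting (k splits, subject level).

    For each split the model is refit on the training fraction and the
    held-out subjects are scored with population (typical) predictions:
    MPE% = 100·mean(log y − log ŷ) measures accuracy (bias) and
    RMSE% = 100·sqrt(mean((log y − log ŷ)²)) precision.  Splits whose fit
    fails are skipped and counted.  The MPE confidence interval is across
    splits.
    """
    from scipy.stats import t as t_dist

    rng = np.random.default_rng(seed)
    ids = table.subject_ids
    n_train = max(2, int(round(train_frac * len(ids))))
    if n_train >= len(ids):
        raise ValueError("training fraction leaves no held-out subjects")
    rows = []
    skipped = 0
    fit_kwargs = {} if estimate is None else {"estimate": estimate}
    for _s in range(k):
        perm = rng.permutation(ids)
        train, test = perm[:n_train], perm[n_train:]
        try:
            res = _fit(table.subset(train), init, init_re,
                       compute_se=False, maxiter=maxiter, **fit_kwargs)
        except EstimationError:
            skipped += 1
            continue
        test_table = table.subset(test)
        obj = LaplaceObjective(test_table, (), False, ())
        pred = obj.predict(_model_dict(res.params, res.re_spec, res.betas),
                           np.zeros((obj.n_subjects, 0)))
        m = obj.obs_mask & (pred > 0) & (obj.obs_dv > 0)
        err = 100.0 * (np.log(obj.obs_dv[m]) - np.log(pred[m]))
        rows.append(dict(
            mpe=float(err.mean()),
            rmse=float(np.sqrt((err ** 2).mean())),
            n_train=len(train), n_test=len(test), n_obs=int(m.sum()),
        ))
    if not rows:
        raise EstimationError("every cross-validation split failed to fit")
    df = pd.DataFrame(rows)
    mpe = df["mpe"].to_numpy()
    mean = float(mpe.mean())
    if len(mpe) > 1:
        half = float(t_dist.ppf(0.975, len(mpe) - 1) * mpe.std(ddof=1) / math.sqrt(len(mpe)))
    else:
        half = float("nan")
    return XvalResult(
        splits=df, mean_mpe=mean, mpe_ci95=(mean - half, mean + half),
        mean_rmse=float(df["rmse"].mean()), skipped=skipped,
    )
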