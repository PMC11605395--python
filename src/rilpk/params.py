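"""Parameter containers for the rilpivirine population-PK model.

Internal unit conventions (used throughout the package):

* time in hours (1 week = 168 h, 1 year = 8766 h),
* dose amounts in mg at the interface, converted to µg internally,
* volumes in litres, clearances in L/h,

so that amount/volume is µg/L ≡ ng/mL and concentrations never need a
conversion factor.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path

import yaml

HOURS_PER_WEEK = 168.0
HOURS_PER_YEAR = 8766.0

__all__ = [
    "PKParameters",
    "RandomEffectsSpec",
    "CovariateModel",
    "IndividualEffects",
    "published_parameters",
    "published_random_effects",
    "published_covariate_model",
    "load_parameters",
    "save_parameters",
    "HOURS_PER_WEEK",
    "HOURS_PER_YEAR",
]


@dataclass(frozen=True)
class PKParameters:
    """Typical (fixed-effect) structural parameters.

    Attributes
    ----------
    CL : float
        Apparent elimination clearance from the central compartment, L/h.
    V3 : float
        Apparent central volume of distribution, L.
    Q : float
        Apparent intercompartmental clearance, L/h.
    V4 : float
        Apparent peripheral volume of distribution, L.
    ka_fast, ka_slow : float
        First-order rate constants of the fast and slow intramuscular
        depot absorption pathways, 1/h.
    F_im_fast : float
        Fraction of an IM dose released through the fast pathway, in (0, 1).
        The remainder drains through the slow depot.
    F_oral : float
        Oral bioavailability relative to IM (IM taken as 100% bioavailable),
        in (0, 1].  Values > 1 can arise for sampled individuals and are
        accepted there; the typical value must be ≤ 1.
    D_oral : float
        Duration of the zero-order oral absorption, h.
    """

    CL: float
    V3: float
    Q: float
    V4: float
    ka_fast: float
    ka_slow: float
    F_im_fast: float
    F_oral: float
    D_oral: float

    def __post_init__(self) -> None:
        for name in ("CL", "V3", "Q", "V4", "ka_fast", "ka_slow", "D_oral"):
            v = getattr(self, name)
            if not (v >= 0.0) or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")
        for name in ("CL", "V3", "V4", "ka_fast", "ka_slow"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.F_im_fast < 1.0:
            raise ValueError("F_im_fast must lie strictly inside (0, 1)")
        if self.F_oral <= 0.0:
            raise ValueError("F_oral must be strictly positive")

    def check_flip_flop(self, strict: bool = False) -> bool:
        """Check ka_slow < ka_fast < ke = CL/V3 (flip-flop absorption).

        Returns True when the condition holds; warns (or raises when
        ``strict``) otherwise.  Under flip-flop the terminal plasma slope
        after an injection reflects the slow absorption rate, not
        elimination.
        """
        ke = self.CL / self.V3
        ok = self.ka_slow < self.ka_fast < ke
        if not ok:
            msg = (
                f"flip-flop ordering violated: ka_slow={self.ka_slow}, "
                f"ka_fast={self.ka_fast}, ke=CL/V3={ke:.5g}"
            )
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
        return ok

    def with_(self, **kwargs) -> "PKParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Variance components of the hierarchical model.

    ``omega_*`` are standard deviations of log-scale (or, for
    ``omega_eta_Ffast``, logit-scale) between-subject random effects;
    ``omega_IOV_CL`` is the SD of the per-injection-occasion log-scale
    effect on clearance.  Residual error is additive for oral records
    (``sigma_add_oral``, ng/mL) and proportional for IM records
    (``sigma_prop_im``, fraction of the prediction).
    """

    omega_F_oral: float = 0.0
    omega_ka_slow: float = 0.0
    omega_CL: float = 0.0
    omega_eta_Ffast: float = 0.0
    omega_IOV_CL: float = 0.0
    sigma_add_oral: float = 0.0
    sigma_prop_im: float = 0.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0.0 or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def as_dict(self) -> dict:
        return asdict(self)

    def with_(self, **kwargs) -> "RandomEffectsSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CovariateModel:
    """Covariate layer of the final model search.

    The only effect retained by the covariate analysis is female sex on
    F_im_fast: the typical fraction is multiplied by (1 + theta_female)
    before the logit transform.  The layer defaults to OFF in all
    downstream machinery because the effect was judged clinically
    irrelevant and excluded from the validated model.
    """

    theta_female: float = 0.0

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class IndividualEffects:
    """Realised random effects of one subject.

    ``kappa_CL`` holds one inter-occasion effect per injection occasion
    (index 0 ↔ occasion 1); oral records belong to occasion 0 and receive
    no IOV.
    """

    eta_F_oral: float = 0.0
    eta_ka_slow: float = 0.0
    eta_CL: float = 0.0
    eta_Ffast: float = 0.0
    kappa_CL: tuple = field(default_factory=tuple)

    def kappa_for(self, occasion: int) -> float:
        """IOV effect for an occasion (1-based); 0.0 for occasion 0 / missing."""
        if occasion <= 0 or occasion > len(self.kappa_CL):
            return 0.0
        return self.kappa_CL[occasion - 1]


# ---------------------------------------------------------------------------
# Published final estimates (packaged defaults)
# ---------------------------------------------------------------------------

_DATA = Path(__file__).parent / "data" / "rilpivirine_final.yaml"


def _published() -> dict:
    with open(_DATA) as fh:
        return yaml.safe_load(fh)


def published_parameters() -> PKParameters:
    """Final typical parameter estimates shipped with the package."""
    d = _published()["typical"]
    return PKParameters(**d)


def published_random_effects() -> RandomEffectsSpec:
    """Final variability estimates, converted from the published CV% scale.

    Log-normal ω are stored in the packaged file as CV% and converted via
    ω = sqrt(ln(1 + CV²)); the logit-scale BSV of F_im_fast is recovered
    from its delta-method CV% ≈ 100·(1−θ)·ω.
    """
    d = _published()
    cv = d["variability_cv_percent"]
    theta_ffast = d["typical"]["F_im_fast"]

    def omega(cv_pct: float) -> float:
        c = cv_pct / 100.0
        return math.sqrt(math.log1p(c * c))

    return RandomEffectsSpec(
        omega_F_oral=omega(cv["F_oral"]),
        omega_ka_slow=omega(cv["ka_slow"]),
        omega_CL=omega(cv["CL"]),
        omega_eta_Ffast=(cv["F_im_fast"] / 100.0) / (1.0 - theta_ffast),
        omega_IOV_CL=omega(cv["IOV_CL"]),
        sigma_add_oral=d["residual"]["sigma_add_oral"],
        sigma_prop_im=d["residual"]["sigma_prop_im"],
    )


def published_covariate_model() -> CovariateModel:
    """Sex effect on F_im_fast from the covariate search (not in the
    validated final model; provided for contrast simulations)."""
    return CovariateModel(theta_female=_published()["covariates"]["theta_female"])


# ---------------------------------------------------------------------------
# Flat-file (de)serialisation
# ---------------------------------------------------------------------------

def save_parameters(path, params: PKParameters, re_spec: RandomEffectsSpec | None = None,
                    covariates: CovariateModel | None = None) -> None:
    """Write a parameter set to YAML or JSON (by extension)."""
    doc: dict = {"typical": params.as_dict()}
    if re_spec is not None:
        doc["random_effects_sd"] = re_spec.as_dict()
    if covariates is not None:
        doc["covariates"] = covariates.as_dict()
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(doc, fh, indent=2)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)


def load_parameters(path):
    """Read a parameter set written by :func:`save_parameters`.

    Returns (PKParameters, RandomEffectsSpec | None, CovariateModel | None).
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    params = PKParameters(**doc["typical"])
    re_spec = (RandomEffectsSpec(**doc["random_effects_sd"])
               if "random_effects_sd" in doc else None)
    cov = CovariateModel(**doc["covariates"]) if "covariates" in doc else None
    return params, re_spec, cov
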