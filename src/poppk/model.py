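"""Population model: fixed effects, covariate structure, random effects,
and the combined proportional + additive residual error model.

Typical parameters are mapped to individual parameters as

* ``CL/F = theta_cl * (WT/70)^0.75 * (1 + theta_flu*FLU) * (1 + theta_dul*DUL) * ...``
* ``V/F  = theta_v  * (WT/70)``
* ``CL_i = CL/F * exp(eta_i)``, ``eta_i ~ N(0, omega2_cl)``

and observations follow ``D = F + F*eps1 + eps2`` with
``Var(D|F) = sigma2_prop*F^2 + sigma2_add``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np
import yaml

from .structural import PKParameters

__all__ = [
    "CovariateEffect",
    "PopulationModel",
    "RandomEffects",
    "ResidualErrorModel",
    "typical_parameters",
    "typical_parameters_from_covariates",
    "individual_parameters",
    "residual_variance",
    "default_quetiapine_model",
]

#: Reference body weight (kg) for allometric scaling.
REFERENCE_WEIGHT = 70.0

#: Fixed allometric exponents by target parameter.
ALLOMETRIC_EXPONENTS = {"cl": 0.75, "v": 1.0}


@dataclass(frozen=True)
class CovariateEffect:
    """One multiplicative covariate term on CL/F or V/F.

    kind:
        ``allometric`` — ``(Z/reference)^coefficient`` with the fixed
        exponent 0.75 (CL/F) or 1 (V/F);
        ``power`` — ``(Z/reference)^coefficient`` with estimated
        exponent, reference at the population median;
        ``linear`` — ``1 + coefficient*Z`` (categorical flags).
    """

    target: str  # "cl" or "v"
    covariate: str  # canonical column name, e.g. "WT", "FLU", "AGE"
    kind: str  # "allometric" | "power" | "linear"
    coefficient: float
    reference: float = 1.0
    estimated: bool = False

    def __post_init__(self):
        if self.target not in ("cl", "v"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.kind not in ("allometric", "power", "linear"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "allometric":
            expected = ALLOMETRIC_EXPONENTS[self.target]
            if self.coefficient != expected:
                raise ValueError(
                    f"allometric exponent on {self.target} must be {expected}")
        if self.kind in ("allometric", "power") and not self.reference > 0:
            raise ValueError("power-form reference must be positive")

    def multiplier(self, z):
        z = np.asarray(z, dtype=float)
        if self.kind == "linear":
            return 1.0 + self.coefficient * z
        if np.any(z <= 0):
            raise ValueError(
                f"covariate {self.covariate} must be positive for power forms")
        return (z / self.reference) ** self.coefficient

    @property
    def label(self) -> str:
        return f"{self.kind}:{self.covariate}->{self.target}"


@dataclass(frozen=True)
class RandomEffects:
    """Subject-level random effect; only CL/F carries inter-individual
    variability (a single eta)."""

    eta_cl: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.eta_cl):
            raise ValueError("eta_cl must be finite")


@dataclass(frozen=True)
class ResidualErrorModel:
    """Combined error: Var(D|F) = sigma2_prop*F^2 + sigma2_add."""

    sigma2_prop: float
    sigma2_add: float
    params_are_sd: bool = False

    @property
    def sigma2_prop_value(self) -> float:
        return self.sigma2_prop ** 2 if self.params_are_sd else self.sigma2_prop

    @property
    def sigma2_add_value(self) -> float:
        return self.sigma2_add ** 2 if self.params_are_sd else self.sigma2_add


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, variance components and covariate structure.

    ``theta_flu``/``theta_dul`` are the fractional-change coefficients
    of the binary comedication flags on CL/F (``None`` means the flag is
    not in the model).  ``covariate_structure`` holds additional
    estimated effects beyond the built-in weight/FLU/DUL terms.

    ``omega2_cl``, ``sigma2_prop`` and ``sigma2_add`` are variances by
    default (NONMEM OMEGA/SIGMA convention); set ``params_are_sd=True``
    to interpret them as standard deviations instead.
    """

    theta_cl: float
    theta_v: float
    ka_fixed: float = 1.46
    theta_flu: float | None = None
    theta_dul: float | None = None
    omega2_cl: float = 0.0
    sigma2_prop: float = 0.0
    sigma2_add: float = 0.0
    covariate_structure: tuple[CovariateEffect, ...] = ()
    params_are_sd: bool = False

    def __post_init__(self):
        if not (self.theta_cl > 0 and self.theta_v > 0 and self.ka_fixed > 0):
            raise ValueError("theta_cl, theta_v and ka_fixed must be positive")
        for name in ("omega2_cl", "sigma2_prop", "sigma2_add"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for coef in (self.theta_flu, self.theta_dul):
            if coef is not None and not (1.0 + coef) > 0:
                raise ValueError("1 + DDI coefficient must stay positive")
        object.__setattr__(self, "covariate_structure",
                           tuple(self.covariate_structure))

    # -- variance accessors honouring the SD/variance switch ------------
    @property
    def omega2_value(self) -> float:
        return self.omega2_cl ** 2 if self.params_are_sd else self.omega2_cl

    @property
    def sigma2_prop_value(self) -> float:
        return self.sigma2_prop ** 2 if self.params_are_sd else self.sigma2_prop

    @property
    def sigma2_add_value(self) -> float:
        return self.sigma2_add ** 2 if self.params_are_sd else self.sigma2_add

    @property
    def residual_model(self) -> ResidualErrorModel:
        return ResidualErrorModel(self.sigma2_prop, self.sigma2_add,
                                  self.params_are_sd)

    def all_effects(self) -> tuple[CovariateEffect, ...]:
        """Built-in weight/FLU/DUL terms followed by extra structure."""
        effects = [
            CovariateEffect("cl", "WT", "allometric", 0.75, REFERENCE_WEIGHT),
            CovariateEffect("v", "WT", "allometric", 1.0, REFERENCE_WEIGHT),
        ]
        if self.theta_flu is not None:
            effects.append(CovariateEffect("cl", "FLU", "linear",
                                           self.theta_flu, estimated=True))
        if self.theta_dul is not None:
            effects.append(CovariateEffect("cl", "DUL", "linear",
                                           self.theta_dul, estimated=True))
        effects.extend(self.covariate_structure)
        return tuple(effects)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        data = {
            "theta_cl": self.theta_cl,
            "theta_v": self.theta_v,
            "ka_fixed": self.ka_fixed,
            "theta_flu": self.theta_flu,
            "theta_dul": self.theta_dul,
            "omega2_cl": self.omega2_cl,
            "sigma2_prop": self.sigma2_prop,
            "sigma2_add": self.sigma2_add,
            "params_are_sd": self.params_are_sd,
            "covariate_structure": [asdict(e) for e in self.covariate_structure],
        }
        return data

    @classmethod
    def from_dict(cls, data: Mapping) -> "PopulationModel":
        data = dict(data)
        effects = tuple(CovariateEffect(**e)
                        for e in data.pop("covariate_structure", []))
        return cls(covariate_structure=effects, **data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PopulationModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_quetiapine_model() -> PopulationModel:
    """Published final quetiapine model used as package default.

    CL/F = 118*(WT/70)^0.75*(1-0.536*FLU)*(1-0.537*DUL) L/h,
    V/F = 2460*(WT/70) L, Ka fixed at 1.46/h, with omega2_CL=0.333,
    sigma2_prop=0.267 and sigma2_add=29.917 (variance convention).
    """
    return PopulationModel(
        theta_cl=118.0,
        theta_v=2460.0,
        ka_fixed=1.46,
        theta_flu=-0.536,
        theta_dul=-0.537,
        omega2_cl=0.333,
        sigma2_prop=0.267,
        sigma2_add=29.917,
    )


def typical_parameters_from_covariates(covariates: Mapping[str, float],
                                       m: PopulationModel) -> PKParameters:
    """Typical (eta=0) parameters for a full covariate mapping.

    Raises ``KeyError`` if the model references a covariate missing
    from the mapping.
    """
    cl = float(m.theta_cl)
    v = float(m.theta_v)
    for effect in m.all_effects():
        mult = float(effect.multiplier(covariates[effect.covariate]))
        if effect.target == "cl":
            cl *= mult
        else:
            v *= mult
    return PKParameters(cl=cl, v=v, ka=m.ka_fixed)


def typical_parameters(weight: float, flu: int, dul: int,
                       m: PopulationModel) -> PKParameters:
    """Typical parameters at a given weight and comedication flags."""
    if not weight > 0:
        raise ValueError("weight must be positive")
    if flu not in (0, 1) or dul not in (0, 1):
        raise ValueError("flu and dul must be 0 or 1")
    for effect in m.covariate_structure:
        if effect.covariate not in ("WT", "FLU", "DUL"):
            raise KeyError(
                f"model uses covariate {effect.covariate!r}; call "
                "typical_parameters_from_covariates with its value")
    return typical_parameters_from_covariates(
        {"WT": float(weight), "FLU": float(flu), "DUL": float(dul)}, m)


def individual_parameters(typ: PKParameters, eta: RandomEffects) -> PKParameters:
    """Apply the log-normal subject deviation: CL_i = CL * exp(eta_cl)."""
    return PKParameters(cl=typ.cl * np.exp(eta.eta_cl), v=typ.v, ka=typ.ka)


def residual_variance(f_pred, m: ResidualErrorModel | PopulationModel):
    """Residual variance sigma2_prop*F^2 + sigma2_add at prediction F."""
    f = np.asarray(f_pred, dtype=float)
    if np.any(f < 0):
        raise ValueError("prediction must be nonnegative")
    out = m.sigma2_prop_value * f * f + m.sigma2_add_value
    return float(out) if np.isscalar(f_pred) else out
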