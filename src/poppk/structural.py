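"""Closed-form one-compartment, first-order absorption kinetics.

Single oral dose, multi-dose superposition, and the steady-state
profile.  All concentrations are ng/mL; doses are mg; internal mass
balance is mg/L, converted exactly once at this module's boundary.
Bioavailability is absorbed into the apparent parameters (CL/F, V/F);
no separate F exists anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PKParameters",
    "Regimen",
    "conc_single_dose",
    "conc_multi_dose",
    "conc_steady_state",
    "MG_PER_L_TO_NG_PER_ML",
]

#: mg/L -> ng/mL conversion, applied exactly once per evaluation.
MG_PER_L_TO_NG_PER_ML = 1000.0

#: Relative |ka-ke| threshold below which the analytic ka==ke limit is used.
DEGENERACY_RTOL = 1e-8


@dataclass(frozen=True)
class PKParameters:
    """Individual PK parameters: CL/F (L/h), V/F (L), Ka (1/h).

    Fields may be scalars or broadcastable numpy arrays (e.g. a vector
    of clearances for a population of virtual subjects).
    """

    cl: float | np.ndarray
    v: float | np.ndarray
    ka: float | np.ndarray

    def __post_init__(self):
        for name in ("cl", "v", "ka"):
            value = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(value)) or not np.all(value > 0.0):
                raise ValueError(f"{name} must be finite and strictly positive")

    @property
    def ke(self) -> float | np.ndarray:
        """Elimination rate constant CL/V (1/h)."""
        return np.asarray(self.cl, float) / np.asarray(self.v, float)


@dataclass(frozen=True)
class Regimen:
    """Repeated identical oral doses: ``dose_amount`` mg every ``interval`` h."""

    dose_amount: float
    interval: float
    n_doses: int

    def __post_init__(self):
        if self.dose_amount < 0:
            raise ValueError("dose_amount must be nonnegative")
        if self.interval <= 0:
            raise ValueError("interval must be positive")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")


def _maybe_scalar(x: np.ndarray, scalar: bool):
    return float(x) if scalar and x.ndim == 0 else x


def conc_single_dose(dose, p: PKParameters, t):
    """Concentration (ng/mL) at time ``t`` hours after a single oral dose.

    Uses ``1000*(dose/V)*(Ka/(Ka-ke))*(exp(-ke t) - exp(-Ka t))`` with
    the analytic limit ``1000*(dose/V)*Ka*t*exp(-Ka t)`` where
    ``|Ka-ke|/Ka`` falls below :data:`DEGENERACY_RTOL`.
    """
    scalar = np.isscalar(t) and np.isscalar(p.cl)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("time must be nonnegative")
    ka = np.asarray(p.ka, dtype=float)
    ke = np.asarray(p.ke, dtype=float)
    diff = ka - ke
    degenerate = np.abs(diff) <= DEGENERACY_RTOL * ka
    safe = np.where(degenerate, 1.0, diff)
    general = (ka / safe) * (np.exp(-ke * t) - np.exp(-ka * t))
    limit = ka * t * np.exp(-ka * t)
    conc = MG_PER_L_TO_NG_PER_ML * (dose / np.asarray(p.v, float)) * np.where(
        degenerate, limit, general)
    return _maybe_scalar(conc, scalar)


def conc_multi_dose(regimen: Regimen, p: PKParameters, t):
    """Concentration under repeated dosing by linear superposition.

    Doses are given at ``0, tau, 2*tau, ...``; contributions from doses
    after ``t`` are zero (causality).  A dose at exactly ``t``
    contributes zero, so sampling at a dosing time reads the pre-dose
    trough.
    """
    scalar = np.isscalar(t) and np.isscalar(p.cl)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("time must be nonnegative")
    total = np.zeros(np.broadcast(t, np.asarray(p.ke)).shape)
    for k in range(regimen.n_doses):
        dt = np.maximum(t - k * regimen.interval, 0.0)
        total = total + conc_single_dose(regimen.dose_amount, p, dt)
    return _maybe_scalar(np.asarray(total), scalar)


def conc_steady_state(dose, tau, p: PKParameters, t_in_interval):
    """Steady-state concentration at ``t_in_interval`` hours into the interval.

    The closed form is the infinite-dose limit of superposition;
    ``t_in_interval = 0`` is the pre-dose trough.
    """
    scalar = np.isscalar(t_in_interval) and np.isscalar(p.cl)
    t = np.asarray(t_in_interval, dtype=float)
    if np.any(t < 0.0) or np.any(t >= tau):
        raise ValueError("t_in_interval must lie in [0, tau)")
    ka = np.asarray(p.ka, dtype=float)
    ke = np.asarray(p.ke, dtype=float)
    ea_tau = np.exp(-ka * tau)
    ek_tau = np.exp(-ke * tau)
    diff = ka - ke
    degenerate = np.abs(diff) <= DEGENERACY_RTOL * ka
    safe = np.where(degenerate, 1.0, diff)
    general = (ka / safe) * (np.exp(-ke * t) / (1.0 - ek_tau)
                             - np.exp(-ka * t) / (1.0 - ea_tau))
    # l'Hopital limit of the accumulation formula as ke -> ka
    limit = (ka * np.exp(-ka * t)
             * (t * (1.0 - ea_tau) + tau * ea_tau) / (1.0 - ea_tau) ** 2)
    conc = MG_PER_L_TO_NG_PER_ML * (dose / np.asarray(p.v, float)) * np.where(
        degenerate, limit, general)
    return _maybe_scalar(conc, scalar)
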