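"""Closed-form macroscopic tumor growth laws and treatment-response formulas.

Two two-parameter growth laws are implemented for a volume ``V(t)`` (volume is
taken proportional to cell number, i.e. constant cellular density):

Gompertz law (GL)
    ``(1/V) dV/dt = k ln(V_inf / V)`` with solution

    ``ln V(t) = ln V_inf + ln(V0 / V_inf) * exp(-k t)``

    ``k`` has dimension 1/day and ``V_inf`` is the carrying capacity (CC),
    the asymptotic volume supported by the local microenvironment.

Logistic law (LL)
    implemented as the exponential relaxation toward the carrying capacity,

    ``V(t) = V_inf + (V0 - V_inf) * exp(-lambda t)``,

    which satisfies ``V(0) = V0`` and ``V(inf) = V_inf`` and reduces exactly
    to ``V0 * exp(-lambda t)`` when ``V_inf -> 0`` (the complete-response
    regime, where the decay rate is ``lambda`` itself).

Therapy enters through a *modified* carrying capacity: after the end of
treatment at ``t*`` the evolution restarts from ``V(t*)`` with the dose
dependent CC ``V_inf(d)``, so post-treatment regression (growth) occurs when
``V_inf(d) < V(t*)`` (``> V(t*)``).  Radiation cell kill per course is
summarised by the linear-quadratic survival model ``-ln S = n (alpha d +
beta d^2)``.

Units are fixed to days and cm^3 (or dimensionless volume ratios); rates are
per day.  Non-positive volumes or rates are hard errors, never clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InvalidParameterError

__all__ = [
    "GrowthLawParams",
    "TreatmentContext",
    "LQParams",
    "gompertz_volume",
    "gompertz_specific_rate",
    "logistic_volume",
    "regression_after_treatment",
    "lq_log_survival",
    "composite_rate",
    "LAWS",
]

LAWS = ("gompertz", "logistic")


@dataclass(frozen=True)
class GrowthLawParams:
    """Parameter set of one growth law.

    Parameters
    ----------
    law : {"gompertz", "logistic"}
    V0 : float
        Initial volume (cm^3, or 1 for normalized series), > 0.
    Vinf : float
        Carrying-capacity volume, > 0.  ``Vinf < V0`` describes regression
        (a therapy-depressed carrying capacity), ``Vinf > V0`` growth.
    rate : float
        Gompertz ``k`` or logistic ``lambda``, per day, > 0.
    """

    law: str
    V0: float
    Vinf: float
    rate: float

    def __post_init__(self):
        if self.law not in LAWS:
            raise InvalidParameterError(f"unknown law {self.law!r}; expected one of {LAWS}")
        for name in ("V0", "Vinf", "rate"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise InvalidParameterError(f"{name} must be finite and > 0, got {value!r}")

    @property
    def log_ratio(self) -> float:
        """``ln(Vinf / V0)``; negative for regression."""
        return math.log(self.Vinf / self.V0)

    def volume(self, t):
        """Volume at time ``t`` (days from the initial condition)."""
        if self.law == "gompertz":
            return gompertz_volume(t, self)
        return logistic_volume(t, self)


@dataclass(frozen=True)
class TreatmentContext:
    """End-of-treatment bookkeeping: ``t* = n tau`` and the volume there.

    Post-treatment formulas take absolute days together with this context so
    that the restart at ``t*`` is explicit (no 0- vs t*-origin ambiguity).
    """

    t_star: float
    V_at_tstar: float
    n_fractions: int | None = None
    tau: float | None = None

    def __post_init__(self):
        if not (np.isfinite(self.t_star) and self.t_star >= 0):
            raise InvalidParameterError(f"t_star must be >= 0, got {self.t_star!r}")
        if not (np.isfinite(self.V_at_tstar) and self.V_at_tstar > 0):
            raise InvalidParameterError(f"V_at_tstar must be > 0, got {self.V_at_tstar!r}")
        if self.n_fractions is not None and self.n_fractions < 0:
            raise InvalidParameterError("n_fractions must be >= 0")
        if self.tau is not None and self.tau <= 0:
            raise InvalidParameterError("tau must be > 0")
        if self.n_fractions is not None and self.tau is not None:
            if not math.isclose(self.t_star, self.n_fractions * self.tau, rel_tol=1e-9, abs_tol=1e-9):
                raise InvalidParameterError(
                    f"t_star={self.t_star} inconsistent with n_fractions*tau="
                    f"{self.n_fractions * self.tau}"
                )


@dataclass(frozen=True)
class LQParams:
    """Linear-quadratic radiosensitivity parameters for a fractionated course."""

    alpha: float  # per Gy
    beta: float  # per Gy^2
    dose_per_fraction: float  # Gy
    n_fractions: int

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise InvalidParameterError("alpha and beta must be >= 0")
        if self.dose_per_fraction < 0:
            raise DomainError("dose must be >= 0")
        if self.n_fractions < 0:
            raise InvalidParameterError("n_fractions must be >= 0")


def _check_times(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise DomainError("times must be finite and >= 0")
    return t


def gompertz_volume(t, p: GrowthLawParams):
    """Gompertz volume at time ``t`` (days): ``V = V0 exp(b (1 - e^{-kt}))``
    with ``b = ln(Vinf/V0)``.  Monotone from ``V0`` toward ``Vinf``."""
    if p.law != "gompertz":
        raise InvalidParameterError("gompertz_volume requires gompertz params")
    t = _check_times(t)
    b = p.log_ratio
    return p.V0 * np.exp(b * (-np.expm1(-p.rate * t)))


def logistic_volume(t, p: GrowthLawParams):
    """Logistic-law volume at time ``t``: ``V = Vinf + (V0 - Vinf) e^{-rate t}``."""
    if p.law != "logistic":
        raise InvalidParameterError("logistic_volume requires logistic params")
    t = _check_times(t)
    return p.Vinf + (p.V0 - p.Vinf) * np.exp(-p.rate * t)


def gompertz_specific_rate(V, Vinf, k):
    """Specific growth rate ``(1/V) dV/dt = k ln(Vinf / V)`` (per day).

    Positive iff ``V < Vinf``, zero at the carrying capacity; its sign is the
    regression criterion after a therapy-modified CC.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0) or Vinf <= 0 or k <= 0:
        raise InvalidParameterError("V, Vinf and k must be > 0")
    return k * np.log(Vinf / V)


def regression_after_treatment(t, ctx: TreatmentContext, Vinf_d: float, k: float):
    """Post-treatment volume ratio ``V(t)/V(t*)`` under a modified CC.

    ``V(t)/V(t*) = exp( ln[Vinf(d)/V(t*)] * (1 - e^{-k (t - t*)}) )`` for
    ``t >= t*``.  The ratio is < 1 for all ``t > t*`` iff ``Vinf_d < V(t*)``
    and tends to ``Vinf_d / V(t*)`` as ``t -> inf``.
    """
    if Vinf_d <= 0 or k <= 0:
        raise InvalidParameterError("Vinf_d and k must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < ctx.t_star):
        raise DomainError(f"t must be >= t_star={ctx.t_star}")
    log_cc_ratio = math.log(Vinf_d / ctx.V_at_tstar)
    return np.exp(log_cc_ratio * (-np.expm1(-k * (t - ctx.t_star))))


def lq_log_survival(p: LQParams) -> float:
    """Linear-quadratic log cell kill ``-ln S = n (alpha d + beta d^2)``."""
    d = p.dose_per_fraction
    return p.n_fractions * (p.alpha * d + p.beta * d * d)


def composite_rate(p: GrowthLawParams) -> float:
    """Effective early-time exponential rate ``k |ln(Vinf/V0)|`` (per day).

    In the strong-regression limit (``Vinf << V0``, ``t << 1/k``) the Gompertz
    solution decays as ``V0 exp(-composite_rate * t)``; it is the only
    identifiable parameter combination when a series is exponential-degenerate.
    For the logistic law the corresponding limit rate is ``rate`` itself.
    """
    if p.law != "gompertz":
        raise InvalidParameterError("composite_rate is defined for gompertz params")
    return p.rate * abs(p.log_ratio)
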