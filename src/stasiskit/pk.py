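"""Steady-state unbound plasma pharmacokinetics over one dosing interval.

All concentrations are unbound (free) and in nM, times in hours, doses in
mg/kg.  The default profile is mono-exponential decay from ``c_max`` at the
start of the interval to ``c_trough`` at its end, which describes the
post-accumulation steady state of a one-compartment model with negligible
absorption time.  A first-order absorption phase (Bateman-shaped interval
profile) is available through :func:`absorption_profile`; flip-flop kinetics
(absorption slower than elimination) are excluded by assumption.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DomainError, FlipFlopError

__all__ = [
    "PKParameters",
    "DoseRegimen",
    "AbsorptionProfile",
    "elimination_rate",
    "concentration_at",
    "steady_state_auc",
    "absorption_profile",
    "unbound",
    "profile_from_regimen",
]


def elimination_rate(c_max: float, c_trough: float, tau: float) -> float:
    """First-order elimination rate constant k = ln(c_max/c_trough)/tau in 1/h.

    For a mono-exponential interval profile this is the unique rate carrying
    ``c_max`` at t=0 to ``c_trough`` at t=tau.  ``c_max == c_trough`` (a
    constant-infusion profile, PTR = 1) gives k = 0.
    """
    if not (c_max > 0 and c_trough > 0):
        raise DomainError("concentrations must be positive")
    if c_max < c_trough:
        raise DomainError("c_max must be >= c_trough")
    if not tau > 0:
        raise DomainError("tau must be positive")
    return math.log(c_max / c_trough) / tau


@dataclass(frozen=True)
class PKParameters:
    """Steady-state unbound plasma profile over one dosing interval.

    Parameters
    ----------
    c_max, c_trough:
        Peak and trough unbound concentrations (nM); ``c_max >= c_trough > 0``.
    tau:
        Dosing interval (h).
    k_a:
        Optional absorption rate (1/h); if given, must exceed the derived
        elimination rate (no flip-flop kinetics).
    fu:
        Optional unbound fraction in (0, 1], recorded for provenance only --
        the concentrations held here are already unbound.
    """

    c_max: float
    c_trough: float
    tau: float
    k_a: float | None = None
    fu: float | None = None

    def __post_init__(self) -> None:
        elimination_rate(self.c_max, self.c_trough, self.tau)  # validates
        if self.k_a is not None and self.k_a <= self.k_e:
            raise FlipFlopError(
                f"k_a={self.k_a} must exceed k_e={self.k_e:.4g} (no flip-flop kinetics)"
            )
        if self.fu is not None and not (0 < self.fu <= 1):
            raise DomainError("fu must lie in (0, 1]")

    @property
    def ptr(self) -> float:
        """Peak-trough ratio c_max/c_trough (>= 1)."""
        return self.c_max / self.c_trough

    @property
    def k_e(self) -> float:
        """Elimination rate constant (1/h)."""
        return elimination_rate(self.c_max, self.c_trough, self.tau)


def concentration_at(t, params: PKParameters):
    """Unbound concentration c_max * exp(-k_e * t) at time t in [0, tau].

    Accepts a scalar or array ``t``; by construction c(0) = c_max and
    c(tau) = c_trough.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > params.tau):
        raise DomainError(f"t must lie in [0, {params.tau}]")
    out = params.c_max * np.exp(-params.k_e * t)
    return float(out) if out.ndim == 0 else out


def steady_state_auc(params: PKParameters) -> float:
    """Interval AUC of the mono-exponential profile (nM*h), closed form.

    AUC = (c_max - c_trough)/k_e, with the constant-infusion limit
    c * tau when PTR = 1.  The average concentration is AUC/tau.
    """
    k = params.k_e
    if k == 0.0:
        return params.c_max * params.tau
    return (params.c_max - params.c_trough) / k


def unbound(total_value: float, fu: float) -> float:
    """Convert a total concentration or exposure to its unbound value.

    All core stasis mathematics operates on unbound quantities; ``fu`` is the
    unbound (free) fraction in (0, 1].
    """
    if not (0 < fu <= 1):
        raise DomainError("fu must lie in (0, 1]")
    return total_value * fu


@dataclass(frozen=True)
class DoseRegimen:
    """Dosing regimen with dose-linear unbound exposure.

    ``auc_dn_ub`` is the dose-normalised unbound interval AUC
    (nM*h per mg/kg), so ``auc_ub = dose * auc_dn_ub``.
    """

    dose: float
    tau: float
    n_intervals: int
    auc_dn_ub: float

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise DomainError("dose must be >= 0")
        if not self.tau > 0:
            raise DomainError("tau must be positive")
        if self.n_intervals < 1:
            raise DomainError("n_intervals must be >= 1")
        if not self.auc_dn_ub > 0:
            raise DomainError("auc_dn_ub must be positive")

    @property
    def auc_ub(self) -> float:
        """Unbound interval AUC at this dose (nM*h)."""
        return self.dose * self.auc_dn_ub

    @property
    def c_average_dn_ub(self) -> float:
        """Dose-normalised unbound average concentration (nM per mg/kg)."""
        return self.auc_dn_ub / self.tau

    @property
    def c_average_ub(self) -> float:
        """Unbound average concentration at this dose (nM)."""
        return self.auc_ub / self.tau


def profile_from_regimen(regimen: DoseRegimen, ptr: float, fu: float | None = None) -> PKParameters:
    """Mono-exponential steady-state profile realising a regimen's exposure.

    Given the unbound interval AUC implied by the dose and a compound
    peak-trough ratio, the trough follows from
    AUC = c_trough * (PTR - 1)/k_e with k_e = ln(PTR)/tau; PTR = 1 is the
    constant-infusion limit where c_max = c_trough = AUC/tau.
    """
    if ptr < 1:
        raise DomainError("ptr must be >= 1")
    if regimen.dose <= 0:
        raise DomainError("profile requires a positive dose")
    auc = regimen.auc_ub
    if ptr == 1.0:
        c = auc / regimen.tau
        return PKParameters(c_max=c, c_trough=c, tau=regimen.tau, fu=fu)
    c_trough = auc * math.log(ptr) / (regimen.tau * (ptr - 1.0))
    return PKParameters(c_max=ptr * c_trough, c_trough=c_trough, tau=regimen.tau, fu=fu)


@dataclass(frozen=True)
class AbsorptionProfile:
    """Periodic steady-state profile with first-order absorption and elimination.

    The infinite superposition of shifted Bateman doses sums (geometric
    series, exact to machine precision) to

        c(t) = A * [ e^{-k_e t} / (1 - e^{-k_e tau})  -  e^{-k_a t} / (1 - e^{-k_a tau}) ]

    on one interval t in [0, tau], with A = dose_scale * k_a/(k_a - k_e).
    The profile is continuous across interval boundaries (c(0) = c(tau), the
    steady-state trough); the peak sits at an interior t_max.
    """

    k_a: float
    k_e: float
    tau: float
    dose_scale: float = 1.0
    t_max: float = field(init=False)
    c_max: float = field(init=False)
    c_trough: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.k_e > 0 and self.tau > 0 and self.dose_scale > 0):
            raise DomainError("k_e, tau and dose_scale must be positive")
        if self.k_a <= self.k_e:
            raise FlipFlopError(
                f"k_a={self.k_a} <= k_e={self.k_e}: flip-flop kinetics excluded"
            )
        if self.k_a < 3.0 * self.k_e:
            warnings.warn(
                "k_a < 3*k_e: absorption and elimination phases are not well "
                "separated; mono-exponential stasis formulas may be strained",
                UserWarning,
                stacklevel=2,
            )
        res = minimize_scalar(
            lambda t: -self._c(t),
            bounds=(0.0, self.tau),
            method="bounded",
            options={"xatol": 1e-10},
        )
        object.__setattr__(self, "t_max", float(res.x))
        object.__setattr__(self, "c_max", float(self._c(res.x)))
        object.__setattr__(self, "c_trough", float(self._c(0.0)))

    def _c(self, t):
        a = np.exp(-self.k_e * np.asarray(t, dtype=float)) / -np.expm1(-self.k_e * self.tau)
        b = np.exp(-self.k_a * np.asarray(t, dtype=float)) / -np.expm1(-self.k_a * self.tau)
        amp = self.dose_scale * self.k_a / (self.k_a - self.k_e)
        return amp * (a - b)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > self.tau):
            raise DomainError(f"t must lie in [0, {self.tau}]")
        out = self._c(t)
        return float(out) if out.ndim == 0 else out

    @property
    def ptr(self) -> float:
        """Realised peak-trough ratio of the steady-state interval profile."""
        return self.c_max / self.c_trough

    @property
    def auc(self) -> float:
        """Interval AUC (equals the single-dose total AUC, dose_scale/k_e)."""
        return self.dose_scale / self.k_e


def absorption_profile(
    k_a: float, k_e: float, tau: float, dose_scale: float = 1.0
) -> AbsorptionProfile:
    """Build the steady-state Bateman-shaped interval profile.

    Requires k_a > k_e (no flip-flop kinetics); warns when k_a < 3*k_e, where
    the separable-phase assumption behind the closed-form stasis laws is
    strained.  The returned object is callable on [0, tau] and reports the
    realised t_max, c_max, c_trough and PTR, which can be fed to the
    closed-form stasis machinery in place of the mono-exponential PTR.
    """
    return AbsorptionProfile(k_a=k_a, k_e=k_e, tau=tau, dose_scale=dose_scale)
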