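"""Core SEIR model with saturated incidence and saturated treatment.

The model tracks susceptible (S), exposed (E), infective (I) and recovered
(R) individuals:

    S' = A - beta*S*I/(1 + alpha*I) - d*S
    E' = beta*S*I/(1 + alpha*I) - (d + epsilon)*E
    I' = epsilon*E - (d + mu + upsilon)*I - r*I/(1 + k*I)
    R' = upsilon*I - d*R + r*I/(1 + k*I)

Infection saturates in I (force of infection beta*S*I/(1+alpha*I) plateaus
as infectives crowd), and treatment saturates too (r*I/(1+k*I) is bounded
by r/k, modelling limited medical capacity; k measures how strongly the
infected are delayed for treatment).

Since R does not feed back into the first three equations, equilibrium and
stability analysis uses the reduced (S, E, I) system; the full 4-compartment
right-hand side is kept for simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np

__all__ = [
    "Parameters",
    "Thresholds",
    "incidence",
    "treatment",
    "rhs_full",
    "rhs_reduced",
    "in_invariant_region",
    "thresholds",
]


@dataclass(frozen=True)
class Parameters:
    """The nine model constants.

    Attributes
    ----------
    A : float
        Recruitment rate of the population (individuals / time), > 0.
    beta : float
        Transmission (contact) rate, > 0.
    alpha : float
        Incidence saturation factor (inhibitory effect), >= 0.
    d : float
        Natural death rate, > 0.
    epsilon : float
        Progression rate from exposed to infective, > 0.
    mu : float
        Disease-related mortality, > 0.
    upsilon : float
        Natural recovery rate of infectives, > 0.
    r : float
        Maximal treatment supply per unit time, > 0.
    k : float
        Treatment saturation factor (delay of treatment), >= 0.
    """

    A: float
    beta: float
    alpha: float
    d: float
    epsilon: float
    mu: float
    upsilon: float
    r: float
    k: float

    def __post_init__(self) -> None:
        for name in ("A", "beta", "d", "epsilon", "mu", "upsilon", "r"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"parameter {name} must be strictly positive, got {v!r}")
        for name in ("alpha", "k"):
            v = getattr(self, name)
            if not (v >= 0 and math.isfinite(v)):
                raise ValueError(f"parameter {name} must be nonnegative, got {v!r}")

    def replace(self, **changes: float) -> "Parameters":
        """Return a copy with the given fields replaced (re-validated)."""
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(changes)
        return Parameters(**current)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class Thresholds:
    """Derived scalar thresholds of the model.

    R0       : basic reproduction number; the disease-free equilibrium is
               locally stable iff R0 < 1.
    R0_star  : sufficient threshold for *global* stability of the
               disease-free point (R0_star >= R0 always, since the treatment
               term in its denominator is evaluated at the crowded limit).
    R0_c     : turning-point value of R0 at which the two endemic branches
               collide (discriminant zero); None when k = 0 (quadratic
               degenerates to linear, no turning point).
    k0       : backward-bifurcation threshold on the treatment-delay factor;
               a backward bifurcation at R0 = 1 occurs iff k > k0.
    k1       : endemic local-stability threshold; the Routh-Hurwitz argument
               applies when k < k1. Zero iff alpha = 0.
    """

    R0: float
    R0_star: float
    R0_c: Optional[float]
    k0: float
    k1: float


def incidence(S: float, I: float, p: Parameters) -> float:
    """Saturated incidence beta*S*I/(1 + alpha*I).

    Reduces to the bilinear rate beta*S*I when alpha = 0.
    """
    if S < 0 or I < 0:
        raise ValueError(f"incidence requires S, I >= 0, got S={S}, I={I}")
    return p.beta * S * I / (1.0 + p.alpha * I)


def treatment(I: float, p: Parameters) -> float:
    """Saturated treatment r*I/(1 + k*I).

    Monotone nondecreasing in I; bounded above by r/k when k > 0 (limited
    medical capacity) and linear (r*I) when k = 0.
    """
    if I < 0:
        raise ValueError(f"treatment requires I >= 0, got I={I}")
    return p.r * I / (1.0 + p.k * I)


def rhs_full(x, p: Parameters) -> np.ndarray:
    """Right-hand side of the 4-compartment (S, E, I, R) system."""
    S, E, I, R = x
    lam = incidence(S, I, p)
    h = treatment(I, p)
    return np.array(
        [
            p.A - lam - p.d * S,
            lam - (p.d + p.epsilon) * E,
            p.epsilon * E - (p.d + p.mu + p.upsilon) * I - h,
            p.upsilon * I - p.d * R + h,
        ]
    )


def rhs_reduced(x, p: Parameters) -> np.ndarray:
    """Right-hand side of the reduced (S, E, I) system.

    R decouples (it appears in no other equation), so the reduced system
    carries the full equilibrium and stability structure.
    """
    S, E, I = x
    lam = incidence(S, I, p)
    return np.array(
        [
            p.A - lam - p.d * S,
            lam - (p.d + p.epsilon) * E,
            p.epsilon * E - (p.d + p.mu + p.upsilon) * I - treatment(I, p),
        ]
    )


def in_invariant_region(x, p: Parameters) -> bool:
    """Membership test for the feasible region Omega.

    Omega = {(S, E, I) : S > 0, E >= 0, I >= 0, S + E + I <= A/d}, which is
    positively invariant for the reduced system.
    """
    S, E, I = x
    return S > 0 and E >= 0 and I >= 0 and (S + E + I) <= p.A / p.d


def thresholds(p: Parameters) -> Thresholds:
    """Evaluate all closed-form thresholds at the given parameters.

    R0   = beta*A*epsilon / (d*(d+epsilon)*(d+mu+upsilon+r))
    R0*  = beta*A*epsilon / (d*(d+epsilon)*(d+mu+upsilon + r/(1+alpha*A/d)))
    k0   = (beta+alpha*d)*(d+mu+upsilon+r) / (d*r)
    k1   = alpha*(d+mu+upsilon+r) / r
    R0_c = 1 - b^2 / (4*a*d*(d+epsilon)*(d+mu+upsilon+r))   (only when a > 0,
           i.e. k > 0; with a, b the endemic-quadratic coefficients)
    """
    A, beta, alpha, d, eps, mu, up, r, k = (
        p.A, p.beta, p.alpha, p.d, p.epsilon, p.mu, p.upsilon, p.r, p.k,
    )
    out = d + mu + up  # total outflow from I other than treatment
    R0 = beta * A * eps / (d * (d + eps) * (out + r))
    R0_star = beta * A * eps / (d * (d + eps) * (out + r / (1.0 + alpha * A / d)))
    k0 = (beta + alpha * d) * (out + r) / (d * r)
    k1 = alpha * (out + r) / r

    R0_c: Optional[float] = None
    if k > 0:
        # local import: equilibria depends on this module
        from .equilibria import quadratic_coefficients

        q = quadratic_coefficients(p)
        R0_c = 1.0 - q.b * q.b / (4.0 * q.a * d * (d + eps) * (out + r))

    return Thresholds(R0=R0, R0_star=R0_star, R0_c=R0_c, k0=k0, k1=k1)
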