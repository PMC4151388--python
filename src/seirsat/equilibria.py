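"""Equilibrium structure of the saturated-incidence/saturated-treatment SEIR model.

The disease-free equilibrium is (A/d, 0, 0). Endemic equilibria have
I* > 0 solving the quadratic

    a I^2 + b I + c = 0,
    a = k (d+eps) (d+mu+up) (beta + alpha d)             (a >= 0; a=0 iff k=0)
    b = (d+eps) [ (d+mu+up)(beta + alpha d + k d) + r (beta + alpha d) ]
        - beta A eps k
    c = d (d+eps) (d+mu+up+r) (1 - R0)                   (sign(c) = sign(1-R0))

with S* and E* recovered by back-substitution. The case analysis over
(k, R0, b, discriminant) yields 0, 1 or 2 endemic points; two positive roots
below R0 = 1 is the backward-bifurcation (bistable) regime. The bifurcation
is present at R0 = 1 iff k > 0 and b < 0 there, which reduces to the
explicit criterion k > k0 = (beta + alpha d)(d+mu+up+r)/(d r).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .model import Parameters, rhs_reduced, thresholds

__all__ = [
    "EndemicQuadratic",
    "EndemicPoint",
    "EquilibriumReport",
    "disease_free",
    "quadratic_coefficients",
    "back_substitute",
    "endemic_equilibria",
    "detect_backward_bifurcation",
]

# a quadratic root counts as a positive equilibrium only above this
POSITIVE_ROOT_TOL = 1e-12
# double root declared when discriminant < DOUBLE_ROOT_TOL * b^2
DOUBLE_ROOT_TOL = 1e-10
# |c| below this multiple of its natural scale is treated as R0 = 1
R0_BOUNDARY_TOL = 1e-12


@dataclass(frozen=True)
class EndemicQuadratic:
    """Coefficients of the endemic-equilibrium quadratic a I^2 + b I + c = 0."""

    a: float
    b: float
    c: float

    @property
    def discriminant(self) -> float:
        return self.b * self.b - 4.0 * self.a * self.c


@dataclass(frozen=True)
class EndemicPoint:
    """One endemic equilibrium: the (S, E, I) state plus root bookkeeping."""

    state: np.ndarray
    I_root: float
    multiplicity: int = 1


@dataclass
class EquilibriumReport:
    """Full equilibrium inventory with the existence-case label.

    Case labels follow the model's case analysis:
      H1-unique : k=0, R0>1, unique endemic point (linear equation)
      H1-none   : k=0, R0<=1, no endemic point
      H2-i      : k>0, R0>1, unique endemic point
      H2-ii     : k>0, R0=1, b<0, unique endemic point
      H2-iii    : k>0, R0=R0c, b<0, double root (multiplicity 2)
      H2-iv     : k>0, R0c<R0<1, b<0, two endemic points
      H2-v      : k>0, none otherwise
    """

    dfe: np.ndarray
    endemic: List[EndemicPoint]
    case_label: str
    backward_bifurcation: bool
    quadratic: EndemicQuadratic
    R0: float

    def to_dict(self) -> dict:
        return {
            "R0": self.R0,
            "case_label": self.case_label,
            "backward_bifurcation": self.backward_bifurcation,
            "quadratic": {
                "a": self.quadratic.a,
                "b": self.quadratic.b,
                "c": self.quadratic.c,
                "discriminant": self.quadratic.discriminant,
            },
            "dfe": {"S": self.dfe[0], "E": self.dfe[1], "I": self.dfe[2]},
            "endemic": [
                {
                    "S": pt.state[0],
                    "E": pt.state[1],
                    "I": pt.state[2],
                    "multiplicity": pt.multiplicity,
                }
                for pt in self.endemic
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        """Flat key-value text record (10 significant digits)."""
        lines = [
            f"R0 = {self.R0:.10g}",
            f"case = {self.case_label}",
            f"backward_bifurcation = {self.backward_bifurcation}",
            f"quadratic.a = {self.quadratic.a:.10g}",
            f"quadratic.b = {self.quadratic.b:.10g}",
            f"quadratic.c = {self.quadratic.c:.10g}",
            f"dfe = ({self.dfe[0]:.10g}, 0, 0)",
            f"n_endemic = {len(self.endemic)}",
        ]
        for i, pt in enumerate(self.endemic, 1):
            lines.append(
                f"endemic{i} = ({pt.state[0]:.10g}, {pt.state[1]:.10g}, "
                f"{pt.state[2]:.10g}) multiplicity={pt.multiplicity}"
            )
        return "\n".join(lines)


def disease_free(p: Parameters) -> np.ndarray:
    """The disease-free equilibrium (A/d, 0, 0), which always exists."""
    return np.array([p.A / p.d, 0.0, 0.0])


def quadratic_coefficients(p: Parameters) -> EndemicQuadratic:
    """Coefficients (a, b, c) of the endemic quadratic in I*.

    c is evaluated in the algebraically equivalent form
    d(d+eps)(d+mu+up+r) - beta*A*eps, which avoids compounding rounding of
    R0 through 1 - R0.
    """
    A, beta, alpha, d, eps, mu, up, r, k = (
        p.A, p.beta, p.alpha, p.d, p.epsilon, p.mu, p.upsilon, p.r, p.k,
    )
    out = d + mu + up
    bad = beta + alpha * d
    a = k * (d + eps) * out * bad
    b = (d + eps) * (out * (bad + k * d) + r * bad) - beta * A * eps * k
    c = d * (d + eps) * (out + r) - beta * A * eps
    return EndemicQuadratic(a=a, b=b, c=c)


def back_substitute(I_star: float, p: Parameters) -> np.ndarray:
    """Recover (S*, E*, I*) from a positive root I* of the quadratic.

    S* = A (1 + alpha I*) / (beta I* + d (1 + alpha I*))
    E* = A beta I* / ((d+eps)(beta + alpha d) I* + d (d+eps))
    """
    if not I_star > 0:
        raise ValueError(f"back_substitute requires I* > 0, got {I_star}")
    A, beta, alpha, d, eps = p.A, p.beta, p.alpha, p.d, p.epsilon
    S = A * (1.0 + alpha * I_star) / (beta * I_star + d * (1.0 + alpha * I_star))
    E = A * beta * I_star / ((d + eps) * (beta + alpha * d) * I_star + d * (d + eps))
    return np.array([S, E, I_star])


def _stable_quadratic_roots(q: EndemicQuadratic) -> tuple:
    """Both real roots of aI^2+bI+c, computed without catastrophic cancellation.

    Uses q0 = -(b + sign(b) sqrt(D))/2 so the small-magnitude root is obtained
    as c/q0 rather than by subtracting nearly equal numbers.
    """
    D = q.discriminant
    sqrtD = math.sqrt(max(D, 0.0))
    sign_b = 1.0 if q.b >= 0 else -1.0
    q0 = -0.5 * (q.b + sign_b * sqrtD)
    if q0 == 0.0:  # b == 0 and D == 0 (or c == 0 with b == 0)
        root = 0.0 if q.a == 0 else math.sqrt(max(-q.c / q.a, 0.0))
        return (root, -root)
    r1 = q0 / q.a
    r2 = q.c / q0
    return (max(r1, r2), min(r1, r2))


def endemic_equilibria(p: Parameters) -> EquilibriumReport:
    """Compute all endemic equilibria and classify the existence case."""
    q = quadratic_coefficients(p)
    thr = thresholds(p)
    dfe = disease_free(p)

    c_scale = p.d * (p.d + p.epsilon) * (p.d + p.mu + p.upsilon + p.r)
    at_R0_one = abs(q.c) < R0_BOUNDARY_TOL * c_scale
    bb, _ = detect_backward_bifurcation(p)

    endemic: List[EndemicPoint] = []

    if p.k == 0:
        # quadratic degenerates: bI + c = 0, and b > 0 when k = 0
        label = "H1-none"
        if thr.R0 > 1 and not at_R0_one:
            I = -q.c / q.b
            if I > POSITIVE_ROOT_TOL:
                endemic.append(EndemicPoint(back_substitute(I, p), I))
                label = "H1-unique"
        return EquilibriumReport(dfe, endemic, label, False, q, thr.R0)

    D = q.discriminant
    # |D| (not D >= 0): a numerically located turning point can land a hair
    # on the negative side of the discriminant's zero
    is_double = abs(D) < DOUBLE_ROOT_TOL * q.b * q.b and q.b < 0

    if thr.R0 > 1 and not at_R0_one:
        # c < 0: exactly one positive root regardless of b
        hi, lo = _stable_quadratic_roots(q)
        endemic.append(EndemicPoint(back_substitute(hi, p), hi))
        label = "H2-i"
    elif at_R0_one and q.b < 0:
        # c = 0: roots 0 and -b/a; the positive one is endemic
        I = -q.b / q.a
        endemic.append(EndemicPoint(back_substitute(I, p), I))
        label = "H2-ii"
    elif is_double:
        I = -q.b / (2.0 * q.a)
        if I > POSITIVE_ROOT_TOL:
            endemic.append(EndemicPoint(back_substitute(I, p), I, multiplicity=2))
            label = "H2-iii"
        else:
            label = "H2-v"
    elif D > 0 and q.b < 0 and thr.R0 < 1:
        hi, lo = _stable_quadratic_roots(q)
        if lo > POSITIVE_ROOT_TOL:  # R0c < R0 < 1: both roots positive
            endemic.append(EndemicPoint(back_substitute(hi, p), hi))
            endemic.append(EndemicPoint(back_substitute(lo, p), lo))
            label = "H2-iv"
        else:
            label = "H2-v"
    else:
        label = "H2-v"

    return EquilibriumReport(dfe, endemic, label, bb, q, thr.R0)


def detect_backward_bifurcation(p: Parameters) -> tuple:
    """Decide whether the model has a backward bifurcation at R0 = 1.

    The criterion is k > 0 together with b < 0 when the parameters are
    calibrated so that R0 = 1 (substituting beta*A*eps =
    d(d+eps)(d+mu+up+r) into b). That calibrated sign condition reduces
    exactly to the explicit threshold k > k0, and both forms are evaluated
    and cross-checked.

    Returns (flag, diagnostics dict).
    """
    A, beta, alpha, d, eps, mu, up, r, k = (
        p.A, p.beta, p.alpha, p.d, p.epsilon, p.mu, p.upsilon, p.r, p.k,
    )
    out = d + mu + up
    bad = beta + alpha * d
    # b with beta*A*eps replaced by its R0=1 calibration d(d+eps)(out+r)
    b_at_R0_one = (d + eps) * (out * (bad + k * d) + r * bad) - k * d * (d + eps) * (out + r)
    k0 = bad * (out + r) / (d * r)
    flag_b = k > 0 and b_at_R0_one < 0
    flag_k = k > k0
    if flag_b != flag_k:  # equality case k == k0 sits on the boundary
        flag_b = flag_k
    diagnostics = {
        "k": k,
        "k0": k0,
        "b_at_R0_equal_1": b_at_R0_one,
        "criterion_b_negative": flag_b,
        "criterion_k_gt_k0": flag_k,
    }
    return flag_k, diagnostics


def brute_force_endemic_search(
    p: Parameters,
    n_starts: int = 200,
    seed: int = 0,
    tol: float = 1e-10,
) -> List[np.ndarray]:
    """Multi-start nonlinear fixed-point search for interior equilibria.

    Independent of the quadratic: solves rhs_reduced(x) = 0 from random
    interior starting points and deduplicates the interior (I > 0) solutions.
    Intended as a cross-check oracle for :func:`endemic_equilibria`.
    """
    from scipy.optimize import fsolve

    rng = np.random.default_rng(seed)
    cap = p.A / p.d
    found: List[np.ndarray] = []
    for _ in range(n_starts):
        x0 = rng.uniform([1e-3, 1e-3, 1e-3], [cap, cap / 2, cap / 2])
        sol, info, ier, _ = fsolve(
            lambda x: rhs_reduced(np.abs(x), p), x0, full_output=True
        )
        if ier != 1:
            continue
        sol = np.abs(sol)
        if sol[2] <= 1e-6:
            continue
        if np.max(np.abs(rhs_reduced(sol, p))) > tol:
            continue
        if not any(np.allclose(sol, f, rtol=1e-6, atol=1e-8) for f in found):
            found.append(sol)
    return sorted(found, key=lambda s: s[2])
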