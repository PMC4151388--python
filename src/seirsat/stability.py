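"""Local and global stability analysis.

Local analysis linearises the reduced (S, E, I) system at an equilibrium.
At the disease-free point the characteristic polynomial factors as
(lambda + d)(lambda^2 + P lambda + Q) with Q > 0 iff R0 < 1, so stability
flips exactly at R0 = 1. At an endemic point the cubic
lambda^3 + a1 lambda^2 + a2 lambda + a3 is tested with the Routh-Hurwitz
criterion (H1 = a1 > 0, H2 = a1 a2 - a3 > 0, H3 = a3 H2 > 0); the theorem
applies for treatment-delay k below k1 = alpha (d+mu+up+r)/r. Eigenvalues
of the Jacobian are always computed as an independent numerical check.

Global analysis provides two certificates:

* a Lyapunov function L = eps E + (d+eps) I, nonincreasing along
  trajectories when R0* < 1, certifying global stability of the
  disease-free point;
* the Li-Muldowney geometric approach for the endemic point: the second
  additive compound of the Jacobian, rescaled by P = diag(1, E/I, E/I),
  has Lozinskii measure (w.r.t. the norm max{|u|, |v|+|w|}) bounded by
  sup{g1, g2}; a negative long-run time average of that bound along a
  trajectory rules out periodic orbits, and with local stability this
  yields global stability. The sufficient parameter conditions are
  R0 > 1, k < k1 and d > r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .model import Parameters, rhs_reduced, thresholds

__all__ = [
    "DFEStabilityReport",
    "EndemicStabilityReport",
    "GeometricCertificate",
    "jacobian",
    "dfe_stability",
    "endemic_stability",
    "lyapunov_dfe_certificate",
    "second_additive_compound",
    "lozinskii_bound",
    "geometric_certificate",
]

FIXED_POINT_TOL = 1e-8  # max-norm residual allowed for an "equilibrium" input


@dataclass(frozen=True)
class DFEStabilityReport:
    P: float
    Q: float
    eigenvalues: Tuple[complex, complex, complex]
    verdict: str  # "stable" | "unstable"

    def to_dict(self) -> dict:
        return {
            "P": self.P,
            "Q": self.Q,
            "eigenvalues": [[z.real, z.imag] for z in self.eigenvalues],
            "verdict": self.verdict,
        }


@dataclass(frozen=True)
class EndemicStabilityReport:
    a1: float
    a2: float
    a3: float
    M: float
    hurwitz: Tuple[float, float, float]
    eigenvalues: Tuple[complex, complex, complex]
    verdict: str  # "stable" | "unstable" | "inconclusive-by-theorem"
    theorem_applies: bool  # k < k1 so the Routh-Hurwitz argument is in force

    def to_dict(self) -> dict:
        return {
            "a1": self.a1,
            "a2": self.a2,
            "a3": self.a3,
            "M": self.M,
            "hurwitz": list(self.hurwitz),
            "eigenvalues": [[z.real, z.imag] for z in self.eigenvalues],
            "verdict": self.verdict,
            "theorem_applies": self.theorem_applies,
        }


@dataclass
class GeometricCertificate:
    """Trace of the Lozinskii-measure bound along one trajectory."""

    times: np.ndarray
    g1: np.ndarray
    g2: np.ndarray
    mu_bound: np.ndarray
    time_average: np.ndarray  # running average of mu_bound past the transient
    certified: bool
    hypotheses: dict  # which sufficient conditions held
    aborted: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "certified": self.certified,
            "hypotheses": self.hypotheses,
            "final_time_average": float(self.time_average[-1])
            if len(self.time_average)
            else None,
            "aborted": self.aborted,
        }


def jacobian(x, p: Parameters) -> np.ndarray:
    """Jacobian of the reduced system at state x = (S, E, I)."""
    S, _, I = x
    u = 1.0 + p.alpha * I
    w = 1.0 + p.k * I
    dlam_dS = p.beta * I / u
    dlam_dI = p.beta * S / (u * u)
    return np.array(
        [
            [-p.d - dlam_dS, 0.0, -dlam_dI],
            [dlam_dS, -(p.d + p.epsilon), dlam_dI],
            [0.0, p.epsilon, -(p.d + p.mu + p.upsilon) - p.r / (w * w)],
        ]
    )


def dfe_stability(p: Parameters) -> DFEStabilityReport:
    """Local stability of the disease-free equilibrium.

    The characteristic equation factors as (lambda+d)(lambda^2+P lambda+Q)=0
    with P = 2d+mu+up+r+eps and Q = (d+eps)(d+mu+up+r) - beta*A*eps/d;
    Q > 0 iff R0 < 1, and then both quadratic roots have negative real part.
    """
    P = 2.0 * p.d + p.mu + p.upsilon + p.r + p.epsilon
    Q = (p.d + p.epsilon) * (p.d + p.mu + p.upsilon + p.r) - p.beta * p.A * p.epsilon / p.d
    disc = complex(P * P - 4.0 * Q) ** 0.5
    eigs = (complex(-p.d), (-P + disc) / 2.0, (-P - disc) / 2.0)
    verdict = "stable" if Q > 0 else "unstable"
    return DFEStabilityReport(P=P, Q=Q, eigenvalues=eigs, verdict=verdict)


def _characteristic_coefficients(x_star, p: Parameters) -> Tuple[float, float, float]:
    """Coefficients a1, a2, a3 of the endemic characteristic cubic."""
    S, _, I = x_star
    u = 1.0 + p.alpha * I
    w = 1.0 + p.k * I
    phi = p.beta * I / u            # force-of-infection derivative in S
    psi = p.beta * S * p.epsilon / (u * u)  # eps * d(incidence)/dI
    sigma = p.d + p.mu + p.upsilon + p.r / (w * w)  # I-equation decay rate
    a1 = (p.d + phi) + (p.d + p.epsilon) + sigma
    a2 = (p.d + phi) * ((p.d + p.epsilon) + sigma) + (p.d + p.epsilon) * sigma - psi
    a3 = (p.d + phi) * ((p.d + p.epsilon) * sigma - psi) + phi * psi
    return a1, a2, a3


def _M_quantity(x_star, p: Parameters) -> float:
    """M = (d+eps)(d+mu+up + r/(1+kI*)^2) - beta S* eps/(1+alpha I*)^2.

    Positive whenever k < k1; appears in a3 = (d+phi) M + phi psi, so M > 0
    forces a3 > 0.
    """
    S, _, I = x_star
    u = 1.0 + p.alpha * I
    w = 1.0 + p.k * I
    return (p.d + p.epsilon) * (p.d + p.mu + p.upsilon + p.r / (w * w)) - (
        p.beta * S * p.epsilon / (u * u)
    )


def endemic_stability(x_star, p: Parameters) -> EndemicStabilityReport:
    """Routh-Hurwitz analysis of an endemic equilibrium.

    The Hurwitz verdict and numerically computed Jacobian eigenvalues are
    both reported; a disagreement (outside a |Re lambda| < 1e-8 tolerance
    band) raises a warning rather than being silently resolved.
    """
    res = np.max(np.abs(rhs_reduced(x_star, p)))
    if res > FIXED_POINT_TOL:
        raise ValueError(
            f"x_star is not an equilibrium (rhs residual {res:.3e} > {FIXED_POINT_TOL})"
        )
    a1, a2, a3 = _characteristic_coefficients(x_star, p)
    M = _M_quantity(x_star, p)
    H1 = a1
    H2 = a1 * a2 - a3
    H3 = a3 * H2
    hurwitz_stable = H1 > 0 and H2 > 0 and H3 > 0

    eigs = np.linalg.eigvals(jacobian(x_star, p))
    max_re = float(np.max(eigs.real))
    eig_stable = max_re < 0

    thr = thresholds(p)
    theorem_applies = p.k < thr.k1

    if hurwitz_stable != eig_stable and abs(max_re) > 1e-8:
        warnings.warn(
            "Routh-Hurwitz verdict disagrees with numerical eigenvalues "
            f"(H=({H1:.3e},{H2:.3e},{H3:.3e}), max Re lambda={max_re:.3e})",
            RuntimeWarning,
        )

    if hurwitz_stable:
        verdict = "stable"
    elif eig_stable and not theorem_applies:
        # sufficient condition k < k1 fails but the point is numerically stable
        verdict = "inconclusive-by-theorem"
    else:
        verdict = "unstable"

    return EndemicStabilityReport(
        a1=a1,
        a2=a2,
        a3=a3,
        M=M,
        hurwitz=(H1, H2, H3),
        eigenvalues=tuple(sorted(map(complex, eigs), key=lambda z: z.real)),
        verdict=verdict,
        theorem_applies=theorem_applies,
    )


def lyapunov_dfe_certificate(
    trajectory, p: Parameters, tol: float = 1e-9
) -> Tuple[Optional[bool], np.ndarray]:
    """Evaluate L = eps E + (d+eps) I along a trajectory.

    When R0* < 1 the function is a Lyapunov function for the disease-free
    point: L is nonincreasing and decays to zero. Returns
    (certified, L values); certified is None when R0* >= 1 (the sufficient
    condition does not apply — evaluation-only mode), else True iff the
    sampled L values are nonincreasing to tolerance.

    `trajectory` is anything with `.states` (n x >=3 array) or a plain array.
    """
    states = np.asarray(getattr(trajectory, "states", trajectory), dtype=float)
    L = p.epsilon * states[:, 1] + (p.d + p.epsilon) * states[:, 2]
    thr = thresholds(p)
    if thr.R0_star >= 1:
        return None, L
    scale = max(1.0, float(L[0]))
    nonincreasing = bool(np.all(np.diff(L) <= tol * scale))
    return nonincreasing, L


def second_additive_compound(J: np.ndarray) -> np.ndarray:
    """Second additive compound of a 3x3 matrix.

    Its eigenvalues are the pairwise sums of the eigenvalues of J; the
    Li-Muldowney criterion applies the Lozinskii measure to a rescaled
    version of this matrix.
    """
    J = np.asarray(J)
    if J.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {J.shape}")
    return np.array(
        [
            [J[0, 0] + J[1, 1], J[1, 2], -J[0, 2]],
            [J[2, 1], J[0, 0] + J[2, 2], J[0, 1]],
            [-J[2, 0], J[1, 0], J[1, 1] + J[2, 2]],
        ]
    )


def lozinskii_bound(x, p: Parameters) -> Tuple[float, float, float]:
    """(g1, g2, max(g1, g2)) at a state with E > 0 and I > 0.

    With B the compound Jacobian rescaled by P = diag(1, E/I, E/I) and the
    norm ||(u,v,w)|| = max{|u|, |v|+|w|}, the Lozinskii measure satisfies
    mu(B) <= sup{g1, g2} where

        g1 = beta S I / ((1+alpha I)^2 E) - beta I/(1+alpha I) - (2d+eps)
        g2 = eps E/I - r/(1+k I)^2 + E'/E - I'/I - (2d+mu+up)
    """
    S, E, I = x
    if E <= 0 or I <= 0:
        raise ValueError(f"lozinskii_bound requires E, I > 0, got E={E}, I={I}")
    u = 1.0 + p.alpha * I
    w = 1.0 + p.k * I
    dS, dE, dI = rhs_reduced(x, p)
    g1 = p.beta * S * I / (u * u * E) - p.beta * I / u - (2.0 * p.d + p.epsilon)
    g2 = (
        p.epsilon * E / I
        - p.r / (w * w)
        + dE / E
        - dI / I
        - (2.0 * p.d + p.mu + p.upsilon)
    )
    return g1, g2, max(g1, g2)


def geometric_certificate(
    p: Parameters,
    x0: Sequence[float],
    t_end: float,
    n_samples: int = 2000,
    transient_fraction: float = 0.2,
    persistence_floor: float = 1e-12,
) -> GeometricCertificate:
    """Li-Muldowney global-stability certificate along one trajectory.

    Integrates the reduced system from x0, evaluates the Lozinskii bound
    sup{g1, g2} at each sample, and accumulates its running time average.
    The first `transient_fraction` of the horizon is discarded before
    averaging (the criterion is an asymptotic time average, so the
    transient is irrelevant). The certificate holds when the sufficient
    conditions (R0 > 1, k < k1, d > r) are met and the final running
    average is negative.
    """
    from .simulate import integrate  # local import to avoid a cycle

    thr = thresholds(p)
    hypotheses = {
        "R0_gt_1": thr.R0 > 1,
        "k_lt_k1": p.k < thr.k1,
        "d_gt_r": p.d > p.r,
    }
    traj = integrate(p, x0, t_end, n_points=n_samples)
    E, I = traj.states[:, 1], traj.states[:, 2]
    if np.any(E <= persistence_floor) or np.any(I <= persistence_floor):
        return GeometricCertificate(
            times=traj.times,
            g1=np.array([]),
            g2=np.array([]),
            mu_bound=np.array([]),
            time_average=np.array([]),
            certified=False,
            hypotheses=hypotheses,
            aborted="trajectory left the persistent interior (E or I ~ 0)",
        )
    g = np.array([lozinskii_bound(x, p) for x in traj.states])
    g1, g2, mu = g[:, 0], g[:, 1], g[:, 2]

    i0 = int(np.searchsorted(traj.times, transient_fraction * t_end))
    i0 = min(max(i0, 0), len(traj.times) - 2)
    t = traj.times[i0:]
    # running average (1/(t - t0)) * integral_{t0}^{t} mu ds, trapezoidal
    seg = np.concatenate(
        [[0.0], np.cumsum(0.5 * (mu[i0 + 1 :] + mu[i0:-1]) * np.diff(t))]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = seg / (t - t[0])
    avg[0] = mu[i0]

    certified = all(hypotheses.values()) and avg[-1] < 0
    return GeometricCertificate(
        times=t,
        g1=g1[i0:],
        g2=g2[i0:],
        mu_bound=mu[i0:],
        time_average=avg,
        certified=certified,
        hypotheses=hypotheses,
    )
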