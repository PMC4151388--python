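"""Trajectory integration, convergence classification, bifurcation scans.

Integration wraps scipy's adaptive solvers (explicit Runge-Kutta by default,
a stiff fallback selectable) at tight tolerances; the reduced 3-compartment
or full 4-compartment system is chosen by the length of the initial state.

Bifurcation scans sweep one parameter, recomputing the endemic quadratic at
every grid point; each root is tagged by the sign of 2aI + b, which is the
slope sign of the branch in the (R0, I) plane: positive on the upper
(stable-side) branch, negative on the lower branch. The turning point where
the two branches collide is the zero of the discriminant, located by
bisection.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .equilibria import EquilibriumReport, endemic_equilibria, quadratic_coefficients
from .model import Parameters, rhs_full, rhs_reduced, thresholds

__all__ = [
    "Trajectory",
    "BranchPoint",
    "BifurcationBranch",
    "integrate",
    "classify_convergence",
    "bifurcation_scan",
    "find_turning_point",
    "sample_initial_conditions",
]

SCAN_PARAMETERS = ("r", "beta", "A")


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # shape (n, 3) or (n, 4)
    metadata: dict = field(default_factory=dict)

    @property
    def S(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def E(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def I(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def R(self) -> Optional[np.ndarray]:
        return self.states[:, 3] if self.states.shape[1] > 3 else None

    def write_csv(self, path) -> None:
        cols = ["t", "S", "E", "I", "R"][: 1 + self.states.shape[1]]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for t, row in zip(self.times, self.states):
                w.writerow([f"{t:.10g}"] + [f"{v:.10g}" for v in row])


@dataclass(frozen=True)
class BranchPoint:
    """One endemic root at one grid value of the scanned parameter."""

    param_value: float
    R0: float
    I_root: float
    slope_sign: int  # sign of 2aI + b: +1 upper branch, -1 lower, 0 turning
    stable_side: bool  # True on the 2aI+b > 0 branch


@dataclass
class BifurcationBranch:
    vary: str
    grid: np.ndarray
    R0: np.ndarray  # R0 at each grid value
    points: List[BranchPoint]
    turning_point: Optional[Tuple[float, float, float]] = None  # (value, R0, I)

    def write_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow([self.vary, "R0", "I_root", "slope_sign", "stable_side"])
            for pt in self.points:
                w.writerow(
                    [
                        f"{pt.param_value:.10g}",
                        f"{pt.R0:.10g}",
                        f"{pt.I_root:.10g}",
                        pt.slope_sign,
                        pt.stable_side,
                    ]
                )


def integrate(
    p: Parameters,
    x0: Sequence[float],
    t_end: float,
    n_points: int = 1000,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    stiff: bool = False,
    t_eval: Optional[Sequence[float]] = None,
) -> Trajectory:
    """Integrate the model from x0 over [0, t_end].

    A 3-vector x0 selects the reduced (S, E, I) system, a 4-vector the full
    (S, E, I, R) system. Adaptive RK45 by default; ``stiff=True`` switches
    to LSODA.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError(f"initial state must be componentwise >= 0, got {x0}")
    if x0.shape == (3,):
        f = lambda t, x: rhs_reduced(np.maximum(x, 0.0), p)
    elif x0.shape == (4,):
        f = lambda t, x: rhs_full(np.maximum(x, 0.0), p)
    else:
        raise ValueError(f"x0 must have 3 or 4 components, got shape {x0.shape}")

    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, max(int(n_points), 2)) if t_end > 0 else [0.0]
    if t_end == 0:
        return Trajectory(np.array([0.0]), x0[None, :], {"parameters": p.to_dict()})

    sol = solve_ivp(
        f,
        (0.0, t_end),
        x0,
        method="LSODA" if stiff else "RK45",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return Trajectory(
        times=sol.t,
        states=sol.y.T,
        metadata={
            "parameters": p.to_dict(),
            "rtol": rtol,
            "atol": atol,
            "method": "LSODA" if stiff else "RK45",
        },
    )


def classify_convergence(
    traj: Trajectory,
    report: EquilibriumReport,
    tol: float = 1e-4,
    tail_fraction: float = 0.1,
) -> str:
    """Name the equilibrium the trajectory tail has settled at, if any.

    Compares the last `tail_fraction` of the samples against the
    disease-free point and each endemic point in `report` (max-norm over the
    (S, E, I) components). Returns "disease-free", "endemic-1" (largest-I
    endemic point), "endemic-2", or "undetermined".
    """
    n_tail = max(int(len(traj.times) * tail_fraction), 1)
    tail = traj.states[-n_tail:, :3]
    targets = [("disease-free", report.dfe)] + [
        (f"endemic-{i}", pt.state) for i, pt in enumerate(report.endemic, 1)
    ]
    for label, target in targets:
        if np.max(np.abs(tail - target[None, :])) < tol:
            return label
    return "undetermined"


def bifurcation_scan(p: Parameters, vary: str, grid: Sequence[float]) -> BifurcationBranch:
    """Sweep one parameter and collect the endemic branch structure.

    For each grid value the thresholds and endemic equilibria are
    recomputed; every positive root I is emitted with the sign of 2aI + b
    (branch slope in the (R0, I) plane). A turning point is located by
    bisection whenever the discriminant changes sign between neighbouring
    grid values in the two-branch (b < 0) regime.
    """
    if vary not in SCAN_PARAMETERS:
        raise ValueError(f"vary must be one of {SCAN_PARAMETERS}, got {vary!r}")
    grid = np.asarray(grid, dtype=float)
    points: List[BranchPoint] = []
    R0s = np.empty_like(grid)
    discs = np.empty_like(grid)
    bs = np.empty_like(grid)
    for j, val in enumerate(grid):
        pj = p.replace(**{vary: float(val)})
        rep = endemic_equilibria(pj)
        q = rep.quadratic
        R0s[j] = rep.R0
        discs[j] = q.discriminant
        bs[j] = q.b
        for pt in rep.endemic:
            s = 2.0 * q.a * pt.I_root + q.b
            sgn = 0 if pt.multiplicity > 1 else (1 if s > 0 else -1)
            points.append(
                BranchPoint(
                    param_value=float(val),
                    R0=rep.R0,
                    I_root=pt.I_root,
                    slope_sign=sgn,
                    stable_side=s > 0,
                )
            )

    turning = None
    if p.k > 0:
        for j in range(len(grid) - 1):
            if discs[j] * discs[j + 1] < 0 and min(bs[j], bs[j + 1]) < 0:
                turning = find_turning_point(p, vary, (grid[j], grid[j + 1]))
                break
    return BifurcationBranch(vary=vary, grid=grid, R0=R0s, points=points, turning_point=turning)


def find_turning_point(
    p: Parameters,
    vary: str,
    bracket: Tuple[float, float],
    rel_tol: float = 1e-10,
) -> Tuple[float, float, float]:
    """Locate the saddle-node turning point of the endemic branch.

    Bisects the discriminant of the endemic quadratic over `bracket` for the
    scanned parameter. Returns (parameter value, R0 there, double root
    I = -b/(2a)).
    """
    if vary not in SCAN_PARAMETERS:
        raise ValueError(f"vary must be one of {SCAN_PARAMETERS}, got {vary!r}")
    if p.k == 0:
        raise ValueError("turning point requires k > 0 (quadratic regime)")

    def disc(val: float) -> float:
        return quadratic_coefficients(p.replace(**{vary: float(val)})).discriminant

    lo, hi = float(bracket[0]), float(bracket[1])
    flo, fhi = disc(lo), disc(hi)
    if flo == 0.0:
        hi = lo
    elif fhi == 0.0:
        lo = hi
    elif flo * fhi > 0:
        raise ValueError(
            f"discriminant does not change sign on bracket ({lo}, {hi}): "
            f"D({lo})={flo:.3e}, D({hi})={fhi:.3e}"
        )
    else:
        while (hi - lo) > rel_tol * max(abs(lo), abs(hi), 1e-300):
            mid = 0.5 * (lo + hi)
            fm = disc(mid)
            if fm == 0.0:
                lo = hi = mid
                break
            if flo * fm < 0:
                hi, fhi = mid, fm
            else:
                lo, flo = mid, fm
    val = 0.5 * (lo + hi)
    pj = p.replace(**{vary: val})
    q = quadratic_coefficients(pj)
    I = -q.b / (2.0 * q.a)
    return val, thresholds(pj).R0, I


def sample_initial_conditions(
    p: Parameters, n: int, seed: int = 0, floor: float = 1e-3
) -> np.ndarray:
    """Seeded sampler of initial states inside the feasible region Omega.

    Used for reproducible basin-of-attraction probes in the bistable regime;
    draws (S, E, I) uniformly from the simplex S+E+I <= A/d with S >= floor.
    """
    rng = np.random.default_rng(seed)
    cap = p.A / p.d
    out = np.empty((n, 3))
    for i in range(n):
        while True:
            x = rng.uniform(0.0, cap, size=3)
            if x.sum() <= cap and x[0] >= floor:
                out[i] = x
                break
    return out
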