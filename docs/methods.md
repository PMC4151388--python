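# Methods

## Model and assumptions

The package analyses a four-compartment SEIR system in which both the
infection process and the treatment process saturate:

* incidence βSI/(1+αI): the force of infection per susceptible plateaus as
  infectives accumulate, standing in for behavioural change and crowding;
  α = 0 recovers the bilinear rate.
* treatment rI/(1+kI): near-linear for small outbreaks, capped at r/k for
  large ones; k measures how strongly the infected are delayed for
  treatment (k = 0 is unlimited linear treatment).

Assumptions: constant recruitment A into the susceptible class; exposed
individuals are not infectious; recovery (natural or by treatment) confers
permanent immunity; all parameters constant in time; no demographic
stochasticity or age structure. Because R feeds back into none of the other
equations, every analytical statement is made on the reduced (S, E, I)
system; the full system is integrated only when a 4-vector initial state is
supplied. The feasible region Ω = {S+E+I ≤ A/d, S>0, E≥0, I≥0} is positively
invariant and all analysis assumes states in its closure.

## Equilibrium structure

Endemic equilibria are roots of aI² + bI + c = 0 with

    a = k(d+ε)(d+μ+υ)(β+αd) ≥ 0        (a = 0 ⇔ k = 0)
    b = (d+ε)[(d+μ+υ)(β+αd+kd) + r(β+αd)] − βAεk
    c = d(d+ε)(d+μ+υ+r)(1−R₀)

S* and E* follow by closed-form back-substitution. The sign pattern of
(c, b, Δ = b²−4ac) yields 0, 1 or 2 endemic points; the two-point window
R₀ᶜ < R₀ < 1 with b < 0 is the backward-bifurcation regime. At R₀ = 1 the
condition b < 0 reduces exactly to k > k₀ = (β+αd)(d+μ+υ+r)/(dr); the
detector evaluates both forms and cross-checks them.

Numerical choices:

* c is evaluated as d(d+ε)(d+μ+υ+r) − βAε rather than through 1−R₀, so scans
  do not compound the rounding of R₀.
* The quadratic is solved in the cancellation-stable form
  q = −(b + sign(b)√Δ)/2, roots q/a and c/q — the small root of a bistable
  scenario (I ≈ 0.086 against b ≈ −0.53) would otherwise lose digits.
* A root counts as positive above 1e−12; a double root is declared when
  |Δ| < 1e−10·b² (the measure-zero tangency cases need slack, and a
  bisection-located turning point may land a hair on either side of Δ = 0);
  R₀ = 1 is declared when |c| < 1e−12·d(d+ε)(d+μ+υ+r).

## Stability analysis

Disease-free point: the characteristic polynomial factors as
(λ+d)(λ²+Pλ+Q) with P = 2d+μ+υ+r+ε and Q ∝ (1−R₀), so the verdict is exact.
Endemic points: the cubic coefficients a₁, a₂, a₃ are evaluated in closed
form and tested with Routh–Hurwitz (H₁ = a₁, H₂ = a₁a₂−a₃, H₃ = a₃H₂, all
positive ⇔ stable); eigenvalues of the Jacobian are always computed
independently and a disagreement outside a |Re λ| < 1e−8 band raises a
warning rather than being silently resolved. The sufficient condition
k < k₁ = α(d+μ+υ+r)/r (which forces the auxiliary quantity
M = (d+ε)(d+μ+υ+r/(1+kI*)²) − βS*ε/(1+αI*)² positive) is reported as a
separate gate: when it fails but the point is numerically stable the verdict
is still "stable" if all Hurwitz quantities are positive (they are a
complete criterion), and "inconclusive-by-theorem" only when the numerical
spectrum is stable while the Hurwitz test is not conclusive.

Global stability uses two sufficient certificates:

* Disease-free: L = εE + (d+ε)I is a Lyapunov function when R₀\* < 1, where
  R₀\* replaces r by its crowded-limit value r/(1+αA/d) in the denominator
  of R₀ (hence R₀\* ≥ R₀). The certificate evaluates L along a trajectory
  and checks monotone decay; when R₀\* ≥ 1 it returns "not applicable"
  rather than a verdict — the condition is sufficient only, and a scenario
  with R₀ < 1 < R₀\* can still empirically converge to the disease-free
  point (the strong-treatment preset does exactly this; the package relies
  on simulation evidence there).
* Endemic: the geometric (compound-matrix) criterion. With
  P = diag(1, E/I, E/I) and B the P-rescaled second additive compound of
  the Jacobian, the Lozinskii measure w.r.t. ‖(u,v,w)‖ = max{|u|, |v|+|w|}
  satisfies μ(B) ≤ sup{g₁, g₂} with

      g₁ = βSI/((1+αI)²E) − βI/(1+αI) − (2d+ε)
      g₂ = εE/I − r/(1+kI)² + E′/E − I′/I − (2d+μ+υ)

  and g₁ ≤ E′/E − d, g₂ ≤ E′/E − (d−r). A negative long-run time average of
  sup{g₁,g₂} rules out periodic orbits; combined with local stability and
  the hypothesis gate (R₀ > 1, k < k₁, d > r) this certifies global
  stability. The certificate integrates one trajectory, discards the first
  20% of the horizon as transient (the criterion is a t→∞ average;
  configurable), and averages by the trapezoid rule. g₁, g₂ are evaluated
  only where E, I > 1e−12; a trajectory touching that floor aborts the
  certificate with a diagnostic instead of dividing by zero. The
  uniform-persistence constant that justifies the interior assumption in
  the certified regime is not itself computed.

## Simulation and scans

Integration uses adaptive RK45 at rtol 1e−9 / atol 1e−12 (LSODA selectable
by flag; the system is not stiff at the shipped parameter scales), sampled
on a uniform grid of 1000 points by default. Convergence classification
compares the final 10% of samples against each known equilibrium at 1e−4
max-norm — the same precision at which the shipped scenarios reproduce
their printed coordinates. Bifurcation scans vary one of {r, β, A},
recompute the quadratic at each grid value and tag each root with the sign
of 2aI + b, which is the branch's slope sign in the (R₀, I) plane (positive
on the upper/stable side, negative on the lower). The turning point solves
Δ(parameter) = 0 by plain bisection to relative tolerance 1e−10; basin
probes draw initial conditions from a seeded uniform sampler over Ω
(default seed 0) for reproducibility.

## Shipped scenarios

The three presets are the package's study conditions, spanning the three
qualitative regimes: `case1` (A=10, β=0.05, α=1.25, d=0.2, ε=1.2, μ=0.2,
υ=0.4, r=2.5, k=1.25) with R₀ < 1 and no endemic state; `case2` (β=0.3,
α=0.8, d=0.5, r=0.1, k=2, rest as case1) with R₀ > 1 and a unique,
geometrically certified endemic state; `case3` (α=0.1, r=1.5, k=2, rest as
case1) with k > k₀, hence backward bifurcation and bistability. In `case2`
the death rate is d = 0.5: the scenario's stated thresholds and equilibrium
coordinates are mutually consistent only with that value, so it is the one
shipped. Default horizons (t_end = 2000) are long enough for every scenario
to settle within the 1e−4 classification tolerance.

## Known limitations

* All certificates are sufficient-condition checks along finitely many
  sampled trajectories, not interval-arithmetic proofs.
* One-parameter natural continuation only; no pseudo-arclength, so branches
  are scanned in the parameter, not arclength, and vertical tangencies are
  resolved by the discriminant bisection rather than by continuation.
* The turning-point value R₀ᶜ is reported both from its closed-form
  expression 1 − b²/[4ad(d+ε)(d+μ+υ+r)] and from the numerically located
  discriminant zero; for families where b varies with the scanned parameter
  these answer different questions (the closed form freezes b at the base
  parameters), and the numerical locator is the one to trust for scans.
* Parameter validation enforces strict positivity (α, k may be 0); the
  model is not meant for, and the code rejects, degenerate rates.
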