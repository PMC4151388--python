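"""Local (Routh-Hurwitz) and global (Lyapunov / geometric) stability analysis."""

import numpy as np
import pytest

from seirsat import (
    dfe_stability,
    disease_free,
    endemic_equilibria,
    endemic_stability,
    geometric_certificate,
    integrate,
    jacobian,
    lozinskii_bound,
    lyapunov_dfe_certificate,
    rhs_reduced,
    second_additive_compound,
    thresholds,
)
from seirsat.stability import _characteristic_coefficients
from conftest import random_parameters


def fd_jacobian(x, p, h=1e-7):
    """Central-difference Jacobian of the reduced right-hand side."""
    x = np.asarray(x, dtype=float)
    J = np.empty((3, 3))
    for j in range(3):
        e = np.zeros(3)
        e[j] = h * max(1.0, abs(x[j]))
        J[:, j] = (rhs_reduced(x + e, p) - rhs_reduced(x - e, p)) / (2 * e[j])
    return J


class TestJacobian:
    def test_matches_finite_differences_at_random_states(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            p = random_parameters(rng)
            x = rng.uniform(0.1, p.A / p.d, size=3)
            np.testing.assert_allclose(jacobian(x, p), fd_jacobian(x, p), rtol=1e-5, atol=1e-6)

    def test_disease_free_specialization(self, case1):
        p = case1
        J = jacobian(disease_free(p), p)
        expected = np.array(
            [
                [-p.d, 0, -p.beta * p.A / p.d],
                [0, -(p.d + p.epsilon), p.beta * p.A / p.d],
                [0, p.epsilon, -(p.d + p.mu + p.upsilon + p.r)],
            ]
        )
        np.testing.assert_allclose(J, expected, rtol=1e-14)

    def test_trace_always_negative(self):
        rng = np.random.default_rng(43)
        for _ in range(100):
            p = random_parameters(rng)
            x = rng.uniform(0, p.A / p.d, size=3)
            assert np.trace(jacobian(x, p)) < 0


class TestDFEStability:
    def test_case1_stable_case2_unstable(self, case1, case2):
        assert dfe_stability(case1).verdict == "stable"
        assert dfe_stability(case2).verdict == "unstable"

    def test_minus_d_always_an_eigenvalue(self):
        rng = np.random.default_rng(47)
        for _ in range(50):
            p = random_parameters(rng)
            rep = dfe_stability(p)
            assert any(abs(z - (-p.d)) < 1e-14 for z in rep.eigenvalues)

    def test_quadratic_constant_sign_tracks_threshold(self):
        rng = np.random.default_rng(53)
        for _ in range(500):
            p = random_parameters(rng)
            rep = dfe_stability(p)
            assert np.sign(rep.Q) == pytest.approx(np.sign(1 - thresholds(p).R0))

    def test_eigenvalues_match_jacobian_spectrum(self, case2):
        rep = dfe_stability(case2)
        eigs = np.sort_complex(np.linalg.eigvals(jacobian(disease_free(case2), case2)))
        np.testing.assert_allclose(np.sort_complex(np.array(rep.eigenvalues)), eigs, atol=1e-10)


class TestEndemicStability:
    def test_case2_endemic_point_stable(self, case2):
        pt = endemic_equilibria(case2).endemic[0]
        rep = endemic_stability(pt.state, case2)
        assert rep.verdict == "stable"
        assert rep.theorem_applies  # k = 2 < k1 = 9.6
        assert all(h > 0 for h in rep.hurwitz)
        assert max(z.real for z in rep.eigenvalues) < 0

    def test_case3_larger_stable_smaller_unstable(self, case3):
        larger, smaller = endemic_equilibria(case3).endemic
        assert endemic_stability(larger.state, case3).verdict == "stable"
        rep2 = endemic_stability(smaller.state, case3)
        assert rep2.verdict == "unstable"
        assert max(z.real for z in rep2.eigenvalues) > 0

    def test_rejects_non_equilibrium_input(self, case2):
        with pytest.raises(ValueError, match="not an equilibrium"):
            endemic_stability((10.0, 1.0, 1.0), case2)

    def test_characteristic_coefficients_match_jacobian_polynomial(self):
        rng = np.random.default_rng(59)
        checked = 0
        for _ in range(2000):
            if checked >= 40:
                break
            p = random_parameters(rng)
            for pt in endemic_equilibria(p).endemic:
                a1, a2, a3 = _characteristic_coefficients(pt.state, p)
                # char poly of J is lambda^3 + a1 lambda^2 + a2 lambda + a3
                coeffs = np.poly(jacobian(pt.state, p))
                np.testing.assert_allclose([a1, a2, a3], coeffs[1:], rtol=1e-9, atol=1e-12)
                checked += 1

    def test_equilibrium_incidence_identity(self):
        """beta*S*eps/(1+alpha I) = (d+eps)(d+mu+up + r/(1+kI)) at any endemic point."""
        rng = np.random.default_rng(61)
        checked = 0
        for _ in range(2000):
            if checked >= 40:
                break
            p = random_parameters(rng)
            for pt in endemic_equilibria(p).endemic:
                S, _, I = pt.state
                lhs = p.beta * S * p.epsilon / (1 + p.alpha * I)
                rhs = (p.d + p.epsilon) * (p.d + p.mu + p.upsilon + p.r / (1 + p.k * I))
                assert lhs == pytest.approx(rhs, rel=1e-9)
                checked += 1

    def test_M_positive_whenever_k_below_k1(self):
        rng = np.random.default_rng(67)
        checked = 0
        for _ in range(4000):
            if checked >= 40:
                break
            p = random_parameters(rng)
            if p.k >= thresholds(p).k1:
                continue
            for pt in endemic_equilibria(p).endemic:
                assert endemic_stability(pt.state, p).M > 0
                checked += 1
        assert checked >= 40

    def test_hurwitz_verdict_matches_eigenvalues_on_random_cubics(self):
        """Routh-Hurwitz sign conditions vs companion-matrix spectra."""
        rng = np.random.default_rng(71)
        agreements = 0
        for _ in range(1000):
            a1, a2, a3 = rng.uniform(-3, 3, size=3)
            roots = np.roots([1.0, a1, a2, a3])
            max_re = roots.real.max()
            if abs(max_re) < 1e-8:
                continue  # tolerance band around the marginal case
            hurwitz = a1 > 0 and (a1 * a2 - a3) > 0 and a3 * (a1 * a2 - a3) > 0
            assert hurwitz == (max_re < 0)
            agreements += 1
        assert agreements > 900


class TestLyapunovCertificate:
    def test_identically_zero_at_disease_free_point(self, case1):
        states = np.tile(disease_free(case1), (10, 1))
        _, L = lyapunov_dfe_certificate(states, case1)
        assert np.all(L == 0)

    def test_positive_definite_on_infected_subspace(self, case1):
        states = np.array([[50.0, 0.0, 0.0], [40.0, 1.0, 0.0], [40.0, 0.0, 1.0]])
        _, L = lyapunov_dfe_certificate(states, case1)
        assert L[0] == 0 and np.all(L[1:] > 0)

    def test_nonincreasing_when_global_threshold_below_one(self, case1):
        # raising the death rate pushes R0* below 1 (stronger dilution)
        p = case1.replace(d=1.0)
        assert thresholds(p).R0_star < 1
        traj = integrate(p, (8.0, 1.0, 1.0), 100, n_points=500)
        certified, L = lyapunov_dfe_certificate(traj, p)
        assert certified is True
        assert L[-1] < 1e-6 * L[0]

    def test_evaluation_only_when_condition_fails(self, case1):
        # case 1 has R0 < 1 but R0* > 1: the sufficient condition is silent
        assert thresholds(case1).R0_star > 1
        traj = integrate(case1, (40.0, 5.0, 5.0), 50, n_points=100)
        certified, L = lyapunov_dfe_certificate(traj, case1)
        assert certified is None
        assert len(L) == len(traj.times)


class TestCompoundMatrix:
    def test_diagonal_case(self):
        comp = second_additive_compound(np.diag([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(comp, np.diag([3.0, 4.0, 5.0]))

    def test_eigenvalues_are_pairwise_sums(self):
        rng = np.random.default_rng(73)
        for _ in range(100):
            J = rng.normal(size=(3, 3))
            lam = np.linalg.eigvals(J)
            pair_sums = np.sort_complex(
                np.array([lam[0] + lam[1], lam[0] + lam[2], lam[1] + lam[2]])
            )
            comp_eigs = np.sort_complex(np.linalg.eigvals(second_additive_compound(J)))
            np.testing.assert_allclose(comp_eigs, pair_sums, rtol=1e-8, atol=1e-8)

    def test_endemic_jacobian_compound_zero_pattern(self, case2):
        """The model Jacobian's compound has zero (3,1) and (1,3)... only where
        the original has zero (2,0)/(0,1) entries: J31=-J20=0, J13=J12... check
        the structural zeros (3,1) entry -J[2,0] = 0 and (1,2)=(J23)."""
        pt = endemic_equilibria(case2).endemic[0]
        J = jacobian(pt.state, case2)
        comp = second_additive_compound(J)
        assert comp[2, 0] == 0  # -J31 with J31 = 0
        assert comp[0, 1] == J[1, 2] and comp[0, 2] == -J[0, 2]
        assert comp[0, 2] == comp[0, 1]  # both equal beta*S/(1+alpha I)^2

    def test_rejects_wrong_shape(self):
        with pytest.raises(ValueError):
            second_additive_compound(np.eye(2))


class TestLozinskiiAndGeometric:
    def test_bounds_from_exposed_growth_rate(self, case2):
        """g1 <= E'/E - d and g2 <= E'/E - (d - r) at sampled interior states."""
        p = case2
        rng = np.random.default_rng(79)
        for _ in range(200):
            x = rng.uniform([0.5, 0.05, 0.05], [p.A / p.d, 5.0, 5.0])
            g1, g2, _ = lozinskii_bound(x, p)
            dE = rhs_reduced(x, p)[1]
            assert g1 <= dE / x[1] - p.d + 1e-10
            assert g2 <= dE / x[1] - (p.d - p.r) + 1e-10

    def test_value_at_case2_equilibrium(self, case2):
        # E' = I' = 0 there, so g2 = eps E*/I* - r/(1+k I*)^2 - (2d+mu+up)
        p = case2
        pt = endemic_equilibria(p).endemic[0]
        S, E, I = pt.state
        g1, g2, mu = lozinskii_bound(pt.state, p)
        expected_g2 = p.epsilon * E / I - p.r / (1 + p.k * I) ** 2 - (2 * p.d + p.mu + p.upsilon)
        assert g2 == pytest.approx(expected_g2, rel=1e-9)
        expected_g1 = (
            p.beta * S * I / ((1 + p.alpha * I) ** 2 * E)
            - p.beta * I / (1 + p.alpha * I)
            - (2 * p.d + p.epsilon)
        )
        assert g1 == pytest.approx(expected_g1, rel=1e-9)
        assert mu == max(g1, g2)

    def test_rejects_boundary_states(self, case2):
        with pytest.raises(ValueError):
            lozinskii_bound((10.0, 0.0, 1.0), case2)

    def test_case2_certificate_holds(self, case2):
        cert = geometric_certificate(case2, (10.0, 1.0, 1.0), 200.0)
        assert cert.certified
        assert all(cert.hypotheses.values())
        assert cert.time_average[-1] < 0

    def test_running_average_bounded_by_exposed_log_growth(self, case2):
        """(1/t)∫ mu ds <= (ln E(t) - ln E(t0))/(t-t0) - (d - r), sampled."""
        p = case2
        cert = geometric_certificate(p, (10.0, 1.0, 1.0), 200.0, n_samples=400)
        traj = integrate(p, (10.0, 1.0, 1.0), 200.0, n_points=400)
        E = np.interp(cert.times, traj.times, traj.states[:, 1])
        with np.errstate(divide="ignore", invalid="ignore"):
            bound = (np.log(E) - np.log(E[0])) / (cert.times - cert.times[0]) - (p.d - p.r)
        ok = np.isfinite(bound)
        assert np.all(cert.time_average[ok] <= bound[ok] + 1e-8)

    def test_hypothesis_gate_blocks_certificate(self, case2):
        # d < r violates the sufficient conditions regardless of the trajectory
        p = case2.replace(r=0.6)  # now r > d = 0.5
        cert = geometric_certificate(p, (10.0, 1.0, 1.0), 100.0)
        assert not cert.hypotheses["d_gt_r"]
        assert not cert.certified
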