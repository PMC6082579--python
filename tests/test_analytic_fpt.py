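import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.integrate import quad

import fpt_recruit as fr
from fpt_recruit import analytic_fpt as afpt

G = fr.CellGeometry()
D_NBS1 = 2.5


class TestLaplaceFlux:
    def test_lambda_zero_limit_is_certain_absorption(self):
        assert fr.laplace_flux(0.0, 17.0, G, D_NBS1) == 1.0

    def test_start_on_absorber(self):
        for lam in (0.0, 0.5, 5.0):
            assert fr.laplace_flux(lam, 5.0, G, D_NBS1) == pytest.approx(1.0)

    def test_high_precision_reference_value(self):
        # frozen from a 40-digit arbitrary-precision evaluation
        assert fr.laplace_flux(0.01, 17.0, G, D_NBS1) == \
            pytest.approx(0.265911884398, rel=1e-10)

    def test_domain_error_outside_shell(self):
        with pytest.raises(ValueError):
            fr.laplace_flux(0.1, 26.0, G, D_NBS1)
        with pytest.raises(ValueError):
            fr.laplace_flux(0.1, 4.0, G, D_NBS1)

    def test_decreasing_in_lambda(self):
        lams = np.geomspace(1e-4, 10, 30)
        vals = fr.laplace_flux(lams, 17.0, G, D_NBS1)
        assert np.all(np.diff(vals) < 0)
        assert np.all(vals > 0) and np.all(vals <= 1)

    def test_large_lambda_free_space_asymptote(self):
        # the outer wall drops out: P → (ra/r0)·exp((ra−r0)√(λ/D))
        r0 = 17.0
        rel_errs = []
        for lam in (1.0, 10.0, 100.0):
            s = math.sqrt(lam / D_NBS1)
            asym = (5.0 / r0) * math.exp((5.0 - r0) * s)
            rel_errs.append(abs(fr.laplace_flux(lam, r0, G, D_NBS1) - asym) / asym)
        assert rel_errs[0] > rel_errs[1] > rel_errs[2]
        assert rel_errs[2] < 1e-10


class TestBesselRoute:
    @pytest.mark.parametrize("r0", [6.0, 11.0, 14.0, 17.0, 20.0, 24.0])
    def test_equals_hyperbolic_route(self, r0):
        lams = np.geomspace(1e-4, 1e2, 41)
        a = fr.laplace_flux(lams, r0, G, D_NBS1)
        b = fr.laplace_flux_bessel(lams, r0, G, D_NBS1)
        assert np.max(np.abs(a - b) / np.abs(a)) < 1e-10

    def test_start_on_absorber(self):
        assert fr.laplace_flux_bessel(1.0, 5.0, G, D_NBS1) == pytest.approx(1.0)

    def test_lambda_zero_rejected(self):
        with pytest.raises(ValueError, match="laplace_flux"):
            fr.laplace_flux_bessel(0.0, 17.0, G, D_NBS1)


class TestSlowRegime:
    def test_reduced_polynomial_exact_coefficients(self):
        c3, c1, c0 = fr.slow_rate_polynomial(G)
        assert c3 == Fraction(3, 2)
        assert c0 == Fraction(46875)
        assert c1 == Fraction(-122375, 30)
        assert round(abs(c1)) == 4079

    def test_rate_value_and_mean(self):
        k = fr.slow_rate(17.0, D_NBS1, G)
        assert k == pytest.approx(2.8143210e-3, rel=1e-6)
        assert 1.0 / k == pytest.approx(355.33, rel=1e-3)

    def test_rate_linear_in_D(self):
        assert fr.slow_rate(17.0, 2 * D_NBS1, G) == \
            pytest.approx(2 * fr.slow_rate(17.0, D_NBS1, G))

    def test_pdf_normalized_and_initial_value(self):
        k = fr.slow_rate(17.0, D_NBS1, G)
        val, _ = quad(lambda t: fr.slow_pdf(t, 17.0, D_NBS1, G), 0, np.inf)
        assert val == pytest.approx(1.0, abs=1e-10)
        assert fr.slow_pdf(0.0, 17.0, D_NBS1, G) == pytest.approx(k)
        assert fr.slow_pdf(1.0 / k, 17.0, D_NBS1, G) == \
            pytest.approx(k / math.e, rel=1e-12)

    def test_quartic_matches_cubic_denominator(self):
        # the pole-expansion quartic and the rate-expression denominator
        # are the same polynomial up to sign, checked symbolically
        import sympy as sp

        R, ra, r0 = sp.symbols("R r_a r_0", positive=True)
        quartic = (4 * R**4 + 12 * R**2 * r0 * ra - 2 * R**3 * (5 * r0 + ra)
                   - r0 * ra * (r0**2 - ra**2) + 2 * R * (r0**3 - 3 * r0 * ra**2))
        cubic_denom = (-4 * R**4 + 10 * R**3 * r0 - 2 * R * r0**3
                       + 2 * R**3 * ra - 12 * R**2 * r0 * ra + r0**3 * ra
                       + 6 * R * r0 * ra**2 - r0 * ra**3)
        assert sp.expand(quartic + cubic_denom) == 0

    def test_rate_from_exact_rational_substitution(self):
        # k = 6·D·r0·ra/|denominator| evaluated in exact arithmetic
        R, ra, r0, D = Fraction(25), Fraction(5), Fraction(17), Fraction(5, 2)
        denom = (-4 * R**4 + 10 * R**3 * r0 - 2 * R * r0**3 + 2 * R**3 * ra
                 - 12 * R**2 * r0 * ra + r0**3 * ra + 6 * R * r0 * ra**2
                 - r0 * ra**3)
        k_exact = 6 * D * r0 * ra / abs(denom)
        assert fr.slow_rate(17.0, 2.5, G) == pytest.approx(float(k_exact), rel=1e-12)


class TestFastRegime:
    def test_vanishes_at_zero(self):
        assert fr.fast_pdf(0.0, 20.0, D_NBS1, G) == 0.0
        assert fr.fast_pdf(1e-8, 20.0, D_NBS1, G) < 1e-300

    def test_mode_location(self):
        # d/dt log p = 0 at (r0−ra)²/(6D) = 15 s for r0 = 20, D = 2.5
        t = np.linspace(1.0, 60.0, 2360)
        p = fr.fast_pdf(t, 20.0, D_NBS1, G)
        assert t[np.argmax(p)] == pytest.approx(15.0, abs=0.05)
        assert afpt.fast_mode(20.0, D_NBS1, G) == pytest.approx(15.0)

    def test_total_mass_is_transient_hitting_probability(self):
        val, _ = quad(lambda t: fr.fast_pdf(t, 20.0, D_NBS1, G), 0, np.inf)
        assert val == pytest.approx(5.0 / 20.0, rel=1e-8)

    def test_prefactor_reduces_to_printed_constant(self):
        # (ra/r0)(r0−ra)/√(4πD t³) = ra(r0−ra)/(r0·√(4π)·√(D t³)):
        # the dimensionless constant is 1/√(4π) = 0.2821 (printed rounded)
        assert 1.0 / math.sqrt(4 * math.pi) == pytest.approx(0.2821, abs=5e-5)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fr.fast_pdf(1.0, 5.0, D_NBS1, G)


class TestRecruitmentCurves:
    def test_nsd_limits(self):
        assert fr.nsd_curve(0.0, 17.0, D_NBS1, G) == 0.0
        assert fr.nsd_curve(1e6, 17.0, D_NBS1, G) == pytest.approx(1.0, abs=1e-8)
        k = fr.slow_rate(17.0, D_NBS1, G)
        assert fr.nsd_curve(1.0 / k, 17.0, D_NBS1, G) == \
            pytest.approx(1 - 1 / math.e, rel=1e-12)

    def test_nfd_limits(self):
        assert fr.nfd_curve(0.0, 20.0, D_NBS1, G) == 0.0
        assert fr.nfd_curve(1e-9, 20.0, D_NBS1, G) < 1e-8
        assert fr.nfd_curve(1e14, 20.0, D_NBS1, G) == pytest.approx(0.25, rel=1e-6)

    def test_nfd_derivative_is_fast_pdf(self):
        for t in (2.0, 10.0, 40.0):
            h = 1e-4 * t
            num = (fr.nfd_curve(t + h, 20.0, D_NBS1, G)
                   - fr.nfd_curve(t - h, 20.0, D_NBS1, G)) / (2 * h)
            assert num == pytest.approx(fr.fast_pdf(t, 20.0, D_NBS1, G), rel=1e-6)

    def test_curves_monotone(self):
        t = np.geomspace(1e-2, 1800, 200)
        assert np.all(np.diff(fr.nsd_curve(t, 17.0, D_NBS1, G)) > 0)
        nfd = fr.nfd_curve(t, 20.0, D_NBS1, G)
        assert np.all(np.diff(nfd) >= 0)  # flat only where underflowed to 0
        assert np.all(np.diff(nfd[nfd > 1e-12]) > 0)


class TestMeanFPT:
    def test_closed_form_values(self):
        assert fr.mean_fpt(17.0, D_NBS1, G) == pytest.approx(276.5176, rel=1e-6)
        assert fr.mean_fpt(20.0, D_NBS1, G) == pytest.approx(287.5, rel=1e-10)

    def test_equals_minus_flux_slope_at_zero(self):
        # five-point stencil at λ=0; negative λ are reached through the
        # complex evaluation path (analytic continuation, well inside the
        # first pole of the transform at −k ≈ −2.8e-3)
        h = 1e-5
        lam = np.array([-2 * h, -h, h, 2 * h], dtype=complex)
        f = fr.laplace_flux(lam, 17.0, G, D_NBS1)
        slope = np.real(-f[3] + 8 * f[2] - 8 * f[1] + f[0]) / (12 * h)
        assert -slope == pytest.approx(fr.mean_fpt(17.0, D_NBS1, G), rel=1e-8)

    def test_differs_from_reciprocal_slow_rate(self):
        # the pole expansion's 1/k (355.3 s) is not the exact first moment
        tau = fr.mean_fpt(17.0, D_NBS1, G)
        assert abs(1.0 / fr.slow_rate(17.0, D_NBS1, G) - tau) > 70.0


class TestNumericalInversion:
    @pytest.mark.parametrize("t", [1.0, 2.0, 5.0])
    def test_matches_levy_density_at_short_times(self, t):
        # the short-time law holds to 1e-3 well inside the regime bound;
        # by t = 10 s the reflecting wall (5 μm from r0 = 20) already lifts
        # the exact density ~3.6% above the free-space asymptote
        num = fr.invert_flux_numeric(t, 20.0, D_NBS1, G)
        assert num == pytest.approx(fr.fast_pdf(t, 20.0, D_NBS1, G), rel=1e-3)

    def test_wall_correction_beyond_levy_regime(self):
        exact = fr.invert_flux_numeric(10.0, 20.0, D_NBS1, G)
        levy = fr.fast_pdf(10.0, 20.0, D_NBS1, G)
        assert exact > levy  # reflection feeds probability back inward
        assert (exact - levy) / levy == pytest.approx(0.0358, abs=0.005)

    def test_density_integrates_to_one(self):
        val, _ = quad(lambda t: fr.invert_flux_numeric(float(t), 17.0,
                                                       D_NBS1, G),
                      1e-3, 6000, limit=300)
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_exponential_tail(self):
        # local log-slope settles to a constant rate at large times
        ts = np.array([700.0, 1100.0, 1500.0])
        p = np.array([fr.invert_flux_numeric(float(t), 17.0, D_NBS1, G)
                      for t in ts])
        slopes = np.diff(np.log(p)) / np.diff(ts)
        assert slopes[0] == pytest.approx(slopes[1], rel=1e-3)

    def test_high_precision_route_agrees(self):
        fast = fr.invert_flux_numeric(5.0, 20.0, D_NBS1, G)
        precise = fr.invert_flux_numeric(5.0, 20.0, D_NBS1, G, precision=30)
        assert fast == pytest.approx(precise, rel=1e-6)

    def test_stehfest_method_selectable(self):
        a = fr.invert_flux_numeric(50.0, 17.0, D_NBS1, G, method="talbot")
        b = fr.invert_flux_numeric(50.0, 17.0, D_NBS1, G, method="stehfest")
        assert a == pytest.approx(b, rel=1e-3)

    def test_invalid_method(self):
        with pytest.raises(ValueError):
            fr.invert_flux_numeric(1.0, 17.0, D_NBS1, G, method="euler")


def _survival_fd(r0: float, times: np.ndarray, D: float, geometry,
                 nr: int = 801, dt: float = 0.05) -> np.ndarray:
    """Crank–Nicolson solver of the backward diffusion equation.

    S(r, t) is the survival probability of a walker started at radius r:
    ∂S/∂t = D (∂²S/∂r² + (2/r) ∂S/∂r), S(ra)=0, ∂S/∂r|_R = 0, S(·,0)=1.
    Independent finite-difference oracle for the accumulated flux
    1 − S(r0, t).
    """
    from scipy import sparse
    from scipy.sparse.linalg import splu

    ra, R = geometry.nucleus_radius_ra, geometry.outer_radius_R
    r = np.linspace(ra, R, nr)
    h = r[1] - r[0]
    ri = r[1:]  # unknowns; Dirichlet S=0 at ra
    n = ri.size
    diag = np.full(n, -2.0 * D / h**2)
    low = D * (1.0 / h**2 - 1.0 / (h * ri))   # coefficient of S_{i-1}
    up = D * (1.0 / h**2 + 1.0 / (h * ri))    # coefficient of S_{i+1}
    A = sparse.diags([low[1:], diag, up[:-1]], [-1, 0, 1], format="lil")
    # reflecting membrane: ghost node S_{N+1} = S_{N-1} folds into row N
    A[n - 1, n - 2] = 2.0 * D / h**2
    A = sparse.csc_matrix(A)
    identity = sparse.identity(n, format="csc")
    lhs = splu(sparse.csc_matrix(identity - 0.5 * dt * A))
    rhs_op = identity + 0.5 * dt * A
    S = np.ones(n)
    out = []
    t_now = 0.0
    for t_target in np.asarray(times, dtype=float):
        while t_now < t_target - 1e-9:
            S = lhs.solve(rhs_op @ S)
            t_now += dt
        out.append(float(np.interp(r0, ri, S)))
    return np.array(out)


class TestPDEOracle:
    def test_accumulated_flux_matches_finite_difference_solution(self):
        times = np.array([5.0, 20.0, 60.0, 150.0, 400.0])
        cdf = fr.numeric_cdf(times, 17.0, D_NBS1, G)
        surv = _survival_fd(17.0, times, D_NBS1, G)
        assert np.max(np.abs((1.0 - surv) - cdf)) < 1e-3


class TestAveragedCurve:
    def test_point_mass_identity(self):
        t = np.geomspace(1.0, 600.0, 40)
        d = fr.TruncatedGaussian(17.0, 0.0, 17.0, 17.0)
        vals, nodes, w = fr.averaged_curve(
            lambda tt, r0: fr.nsd_curve(tt, r0, D_NBS1, G), d, t)
        assert np.allclose(vals, fr.nsd_curve(t, 17.0, D_NBS1, G))
        assert list(nodes) == [17.0] and list(w) == [1.0]

    def test_mixture_of_monotone_curves_is_monotone(self):
        t = np.geomspace(1.0, 1800.0, 60)
        d = fr.start_distribution(fr.NBS1)
        vals, _, _ = fr.averaged_curve(
            lambda tt, r0: fr.nsd_curve(tt, r0, D_NBS1, G), d, t)
        assert np.all(np.diff(vals) > 0)

    def test_bounded_by_extreme_starts(self):
        # recruitment is monotone in r0, so the mixture lies between the
        # nearest-start and farthest-start curves at every time
        t = np.geomspace(1.0, 1800.0, 50)
        d = fr.start_distribution(fr.NBS1)
        curve = lambda tt, r0: fr.numeric_cdf(tt, r0, D_NBS1, G)
        vals, _, _ = fr.averaged_curve(curve, d, t)
        hi = curve(t, 14.0)
        lo = curve(t, 20.0)
        assert np.all(vals <= hi + 1e-9) and np.all(vals >= lo - 1e-9)

    def test_weights_sum_to_one(self):
        t = np.array([1.0, 10.0])
        d = fr.start_distribution(fr.MRE11)
        _, _, w = fr.averaged_curve(
            lambda tt, r0: fr.nsd_curve(tt, r0, 2.0, G), d, t)
        assert w.sum() == pytest.approx(1.0)
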