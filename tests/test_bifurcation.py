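"""Critical parameter values, map derivatives g'', g''' and classification."""

import math
import warnings

import numpy as np
import pytest

from sispulse import (
    classify_bifurcation,
    critical_A,
    critical_q,
    critical_ST,
    derivative_P1,
    floquet_mu2,
    g_second_zero,
    mu2_partial,
    scan,
    scan2d,
)
from sispulse.bifurcation import (
    K_of_q,
    ST_bar_roots,
    _B1_of_A,
    _B2_of_A,
    mu2_of,
    q_tilde,
)


class TestPartials:
    @pytest.mark.parametrize("wrt", ["q", "S_T", "A"])
    def test_matches_finite_difference(self, fig1, fig2b, wrt, rng_params):
        for p in [fig1, fig2b] + rng_params(5):
            h = 1e-6 * max(1.0, getattr(p, wrt))
            fd = (mu2_of(p, wrt, getattr(p, wrt) + h) - mu2_of(p, wrt, getattr(p, wrt) - h)) / (2 * h)
            assert mu2_partial(p, wrt) == pytest.approx(fd, rel=1e-6)

    def test_q_slope_vanishes_at_q_tilde(self, fig1):
        qt = q_tilde(fig1)
        assert qt == pytest.approx(0.1, rel=1e-12)  # 1 - 7.2/8
        assert mu2_partial(fig1.replace(q=qt), "q") == pytest.approx(0.0, abs=1e-12)

    def test_q_slope_sign_from_printed_factor(self, fig1):
        # beta (1-q) S_T - d - v - c/b = 6.24 - 7.2 < 0 at the baseline
        assert mu2_partial(fig1, "q") < 0

    def test_B2_differentiates_B1(self, fig1):
        h = 1e-6
        for A in (6.0, 7.0, 9.0):
            fd = (_B1_of_A(fig1, A + h) - _B1_of_A(fig1, A - h)) / (2 * h)
            a = fig1.d * (1 - fig1.q) * fig1.S_T
            b = fig1.d * fig1.S_T
            pred = fig1.q * fig1.S_T * _B2_of_A(fig1, A) / ((A - a) ** 2 * (A - b) ** 2)
            assert pred == pytest.approx(fd, rel=1e-6)


class TestCriticalQ:
    def test_fig1_root(self, fig1):
        res = critical_q(fig1)
        q1 = res.critical_value
        assert 0.22 < q1 < 0.23
        assert abs(mu2_of(fig1, "q", q1) - 1) < 1e-8
        # stability flips across the root
        assert mu2_of(fig1, "q", q1 - 1e-3) > 1 > mu2_of(fig1, "q", q1 + 1e-3)

    def test_no_root_when_threshold_low(self, fig1):
        # S_T = 7 < (b(d+v)+c)/(b beta) = 7.2: mu2 decreasing on (0,1)
        res = critical_q(fig1.replace(S_T=7.0))
        assert res.critical_value is None
        assert "decreasing" in res.existence_case

    def test_no_root_when_mu2_at_one_large(self, fig1):
        # push S_T near A/d so the Delta1 factor dominates at q = 1
        p = fig1.replace(S_T=9.9)
        assert mu2_of(p, "q", 1.0) >= 1
        res = critical_q(p)
        assert res.critical_value is None
        assert "unstable for all q" in res.existence_case

    def test_mu2_monotone_structure_in_q(self, fig1):
        """mu2(q) increases on (0, q~) and decreases on (q~, 1)."""
        qt = q_tilde(fig1)
        up = [mu2_of(fig1, "q", q) for q in np.linspace(qt / 10, qt * 0.95, 6)]
        down = [mu2_of(fig1, "q", q) for q in np.linspace(qt * 1.05, 0.98, 8)]
        assert all(a < b for a, b in zip(up, up[1:]))
        assert all(a > b for a, b in zip(down, down[1:]))


class TestCriticalST:
    def test_fig1_quadratic_roots_and_ordering(self, fig1):
        lo, hi = ST_bar_roots(fig1)
        assert lo == pytest.approx(5.2550749312, rel=1e-8)
        assert hi == pytest.approx(17.5654378893, rel=1e-8)
        assert 0 < lo < fig1.A / fig1.d < hi

    def test_fig1_root(self, fig1):
        res = critical_ST(fig1)
        st = res.critical_value
        assert 7.9 < st < 8.0
        assert abs(mu2_of(fig1, "S_T", st) - 1) < 1e-8
        assert mu2_of(fig1, "S_T", st - 1e-3) < 1 < mu2_of(fig1, "S_T", st + 1e-3)

    def test_requires_R0_above_one(self, fig1):
        with pytest.raises(ValueError):
            critical_ST(fig1.replace(beta=0.1))

    def test_K_properties(self):
        assert K_of_q(0.0) == 1.0
        qs = np.linspace(0.0, 0.999, 50)
        Ks = [K_of_q(q) for q in qs]
        assert all(a > b for a, b in zip(Ks, Ks[1:]))  # strictly decreasing
        assert all(k < 1 for k in Ks[1:])


class TestCriticalA:
    def test_fig1_root(self, fig1):
        res = critical_A(fig1)
        a = res.critical_value
        assert 7.2 < a < 7.4
        assert abs(mu2_of(fig1, "A", a) - 1) < 1e-8
        assert mu2_of(fig1, "A", a - 1e-3) > 1 > mu2_of(fig1, "A", a + 1e-3)

    def test_left_endpoint_divergence(self, fig1):
        # mu2 ~ eps^-expo as A -> (d S_T)+ (expo = 1 for the baseline)
        assert mu2_of(fig1, "A", fig1.d * fig1.S_T + 1e-6) > 1e4
        ratio = mu2_of(fig1, "A", fig1.d * fig1.S_T + 1e-8) / mu2_of(
            fig1, "A", fig1.d * fig1.S_T + 1e-6
        )
        assert ratio == pytest.approx(100.0, rel=1e-3)

    def test_tail_limit_is_one(self, fig1):
        """mu2(A) -> 1 as A -> infinity: the Delta1 exponent grows like A
        while ln(Delta1) decays like 1/A, their product cancelling the
        exp(-beta q S_T/(d+theta)) factor exactly.  The residual rate is
        ln mu2 ~ C/A with C = d q S_T (beta(2-q)S_T/2 - d - v - c/b)/(d+theta)
        (negative for the baseline, so the approach is from below and the
        critical A* stays unique)."""
        sat = fig1.d + fig1.v + fig1.c / fig1.b
        C = (fig1.d * fig1.q * fig1.S_T
             * (fig1.beta * (2 - fig1.q) * fig1.S_T / 2 - sat)
             / (fig1.d + fig1.theta))
        assert C < 0
        for A in (1e4, 1e5):
            assert math.log(mu2_of(fig1, "A", A)) == pytest.approx(C / A, rel=1e-3)


class TestMapCurvature:
    def test_g2_routes_agree(self, fig1, fig2b):
        """Quadrature of m(s) dI/dI0 vs second finite difference of the
        map: two independent numerical routes to g''(0)."""
        for p in (fig1, fig2b):
            g2_quad = g_second_zero(p)
            g2_fd = derivative_P1(0.0, p, order=2)
            assert g2_quad == pytest.approx(g2_fd, rel=1e-2)

    def test_g2_vanishes_with_q(self, fig1):
        from sispulse.params import ModelParams

        tiny = ModelParams(**{**fig1.as_dict(), "q": 1e-8})
        assert abs(g_second_zero(tiny)) < 1e-6

    def test_m_of_s_matches_symbolic_second_derivative(self, fig1):
        """m(s) equals the symbolic d^2(F2/F1)/dI^2 at I = 0."""
        sympy = pytest.importorskip("sympy")
        from sispulse.bifurcation import _m_of_s

        S, I = sympy.symbols("S I", positive=True)
        p = fig1
        F1 = p.A - p.d * S - p.beta * S * I + p.v * I + p.theta * (p.A / p.d - S - I) \
            + p.c * I / (p.b + I)
        F2 = p.beta * S * I - (p.d + p.v) * I - p.c * I / (p.b + I)
        m_sym = sympy.diff(F2 / F1, I, 2).subs(I, 0)
        for s in (6.3, 7.0, 7.9):
            assert _m_of_s(s, p) == pytest.approx(float(m_sym.subs(S, s)), rel=1e-10)


class TestClassification:
    def test_cross_derivative_signs(self, fig1):
        """d(mu2)/d(alpha) at the critical point: negative for q and A,
        positive for S_T."""
        assert classify_bifurcation(fig1, "q").mu2_cross_slope == -1
        assert classify_bifurcation(fig1, "S_T").mu2_cross_slope == 1
        assert classify_bifurcation(fig1, "A").mu2_cross_slope == -1

    def test_fig1_family_transcritical(self, fig1):
        """g''(0) > 0 at all three critical points of the fig1 family, so
        each bifurcation is transcritical, consistent between the
        quadrature and finite-difference routes."""
        for wrt in ("q", "S_T", "A"):
            res = classify_bifurcation(fig1, wrt)
            assert res.bif_type == "transcritical"
            p_star = fig1.replace(**{wrt: res.critical_value})
            g2_fd = derivative_P1(0.0, p_star, order=2)
            assert np.sign(g2_fd) == np.sign(res.g2)

    def test_critical_manifold_consistency(self, fig1):
        """The baseline (q, S_T, A) = (0.22, 8, 7) sits within 2% of each
        critical slice, consistent with mu2 barely above 1."""
        assert classify_bifurcation(fig1, "q").critical_value == pytest.approx(0.22, rel=0.02)
        assert classify_bifurcation(fig1, "S_T").critical_value == pytest.approx(8.0, rel=0.02)
        assert classify_bifurcation(fig1, "A").critical_value == pytest.approx(7.0, rel=0.05)

    def test_no_critical_point_passthrough(self, fig1):
        res = classify_bifurcation(fig1.replace(S_T=7.0), "q")
        assert res.critical_value is None and res.bif_type is None


class TestScan:
    def test_ST_scan_single_crossing(self, fig1):
        df = scan(fig1, "S_T", np.linspace(6.0, 9.5, 36))
        sign_changes = np.nonzero(np.diff(np.sign(df["mu2"].to_numpy() - 1)))[0]
        assert len(sign_changes) == 1
        lo = df["S_T"].iloc[sign_changes[0]]
        assert 7.89 < lo < 8.0  # crossing inside (7.9, 8.0); grid step 0.1

    def test_q_scan_monotone_after_turning_point(self, fig1):
        df = scan(fig1, "q", np.linspace(0.12, 0.98, 30))
        mu = df["mu2"].to_numpy()
        assert all(a > b for a, b in zip(mu, mu[1:]))

    def test_A_scan_single_crossing(self, fig1):
        df = scan(fig1, "A", np.linspace(5.7, 12.0, 64))
        mu = df["mu2"].to_numpy()
        sign_changes = np.nonzero(np.diff(np.sign(mu - 1)))[0]
        assert len(sign_changes) == 1

    def test_scan_never_aborts(self, fig1):
        # grid crossing the S_T >= A/d invalid region: rows get a status
        df = scan(fig1, "S_T", [9.0, 10.5])
        assert df["status"].iloc[0] == "ok"
        assert df["status"].iloc[1] != "ok"

    def test_scan_with_fixed_points(self, fig2b):
        df = scan(fig2b, "S_T", [6.3, 8.0], with_fixed_points=True, fp_grid_size=20)
        assert df["n_fixed_points"].tolist() == [0, 1]

    def test_scan2d_long_format(self, fig1):
        df = scan2d(fig1, ("q", "S_T"), [0.2, 0.3], [7.0, 8.0, 9.0])
        assert len(df) == 6
        assert set(df.columns) >= {"q", "S_T", "mu2"}
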