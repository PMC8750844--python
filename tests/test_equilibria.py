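"""Local quadratic derivative fits, CIs, equilibrium points and windows."""

import numpy as np
import pytest
from scipy import stats

from dmrsmooth.curve import DifferenceCurve, KernelConfig, plan_segments
from dmrsmooth.equilibria import (
    DegenerateFitError,
    DerivativeCI,
    DerivativeTrack,
    EquilibriumPoint,
    derivative_ci,
    derivative_track,
    find_equilibrium_points,
    invert_confidence_window,
    local_quadratic_fit,
)


def quad_fit_oracle(pos, d, x0, h):
    """Explicit 3x3 weighted normal equations, no shared code with the fit."""
    w = np.exp(-0.5 * ((pos - x0) / h) ** 2)
    X = np.stack([np.ones_like(pos), pos - x0, (pos - x0) ** 2], axis=1)
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * d)
    alpha = np.linalg.solve(A, b)
    resid = d - X @ alpha
    sigma2 = float(np.sum(w * resid**2) / (np.sum(w) - 3))
    Ainv = np.linalg.inv(A)
    B = X.T @ ((w**2)[:, None] * X)
    cov = Ainv @ B @ Ainv * sigma2
    return alpha, float(np.sqrt(max(cov[1, 1], 0.0)))


def make_track(a1, se=None, pos=None, level=0.95):
    """Derivative track straight from coefficient arrays for rule tests."""
    a1 = np.asarray(a1, dtype=float)
    n = a1.shape[0]
    se = np.full(n, 0.1) if se is None else np.asarray(se, dtype=float)
    pos = np.arange(n, dtype=float) * 100.0 if pos is None else np.asarray(pos, dtype=float)
    z = stats.norm.ppf(0.5 + level / 2)
    safe = np.where(se > 0, se, np.inf)
    p = 2 * stats.norm.sf(np.abs(a1) / safe)
    return DerivativeTrack(
        site_index=np.arange(n),
        pos=pos,
        alpha0=np.zeros(n),
        alpha1=a1,
        alpha2=np.zeros(n),
        se_alpha1=se,
        ci_l=a1 - z * se,
        ci_u=a1 + z * se,
        p_value=p,
        level=level,
    )


class TestLocalQuadraticFit:
    cfg = KernelConfig(h0=300.0, min_influence=10)

    def test_exact_quadratic_recovered(self, rng):
        pos = np.sort(rng.uniform(0, 2000, 40))
        x0 = 1000.0
        y = 2.0 + 3.0 * (pos - x0) + 4.0 * (pos - x0) ** 2
        fit = local_quadratic_fit(pos, y, x0, self.cfg)
        assert (fit.alpha0, fit.alpha1, fit.alpha2) == pytest.approx((2.0, 3.0, 4.0), abs=1e-8)
        assert fit.se_alpha1 == pytest.approx(0.0, abs=1e-8)

    def test_constant_data(self, rng):
        pos = np.sort(rng.uniform(0, 2000, 30))
        fit = local_quadratic_fit(pos, np.full(30, 0.7), 900.0, self.cfg)
        assert (fit.alpha0, fit.alpha1, fit.alpha2) == pytest.approx((0.7, 0.0, 0.0), abs=1e-10)

    def test_matches_normal_equation_oracle(self, rng):
        pos = np.sort(rng.uniform(0, 3000, 30))
        d = rng.normal(0, 0.3, 30)
        cfg = KernelConfig(h0=500.0, min_influence=5)
        for x0 in (400.0, 1500.0, 2800.0):
            fit = local_quadratic_fit(pos, d, x0, cfg)
            alpha, se = quad_fit_oracle(pos, d, x0, fit.h_used)
            assert (fit.alpha0, fit.alpha1, fit.alpha2) == pytest.approx(tuple(alpha), abs=1e-8)
            assert fit.se_alpha1 == pytest.approx(se, abs=1e-8)

    def test_increasing_curve_positive_derivative(self):
        pos = np.linspace(0, 4000, 120)
        y = 0.2 + 1e-4 * pos  # strictly increasing, noiseless
        cfg = KernelConfig(h0=300.0, min_influence=10)
        for x0 in pos[10:-10:17]:
            assert local_quadratic_fit(pos, y, float(x0), cfg).alpha1 > 0

    def test_degenerate_design_raises(self):
        with pytest.raises(DegenerateFitError):
            local_quadratic_fit(np.array([1.0, 1.0, 1.0]), np.ones(3), 1.0, self.cfg)


class TestDerivativeCI:
    def _fit(self, a1, se):
        from dmrsmooth.equilibria import LocalQuadraticFit

        return LocalQuadraticFit(0.0, 0.0, a1, 0.0, se, 10.0, 100.0)

    def test_null_case_symmetric(self):
        ci = derivative_ci(self._fit(0.0, 0.1))
        assert (ci.l, ci.u) == pytest.approx((-0.196, 0.196), abs=1e-3)
        assert ci.p_value == pytest.approx(1.0)
        assert ci.contains_zero

    def test_normal_quantile_arithmetic(self):
        ci = derivative_ci(self._fit(0.3, 0.1))
        assert (ci.l, ci.u) == pytest.approx((0.104, 0.496), abs=1e-3)
        assert ci.p_value == pytest.approx(2 * (1 - stats.norm.cdf(3.0)), rel=1e-9)
        assert ci.p_value == pytest.approx(0.0027, abs=1e-4)
        assert not ci.contains_zero

    def test_zero_se_limits(self):
        ci = derivative_ci(self._fit(0.5, 0.0))
        assert ci.p_value == 0.0 and (ci.l, ci.u) == (0.5, 0.5)
        ci0 = derivative_ci(self._fit(0.0, 0.0))
        assert ci0.p_value == 1.0 and ci0.contains_zero

    def test_duality_ci_contains_zero_iff_p_above_alpha(self, rng):
        for _ in range(200):
            a1, se = rng.normal(0, 0.2), rng.uniform(0.01, 0.3)
            ci = derivative_ci(self._fit(a1, se))
            assert ci.contains_zero == (ci.p_value > 0.05)


class TestFindEquilibriumPoints:
    def test_monotone_derivative_no_points(self):
        tr = make_track([0.9, 0.7, 0.5, 0.4], se=[0.05] * 4)
        assert find_equilibrium_points(tr) == []

    def test_sign_change_picks_min_abs_derivative_with_ci_zero(self):
        # CIs contain zero at the middle two sites; crossing between them
        tr = make_track([0.5, 0.2, -0.1, -0.4], se=[0.05, 0.15, 0.15, 0.05])
        pts = find_equilibrium_points(tr)
        assert len(pts) == 1
        assert pts[0].kind == "maximum"
        assert pts[0].track_idx == 2  # |−0.1| < |0.2|
        assert pts[0].ci.contains_zero

    def test_minimum_detected_on_rising_crossing(self):
        tr = make_track([-0.5, -0.1, 0.2, 0.5], se=[0.05, 0.15, 0.15, 0.05])
        pts = find_equilibrium_points(tr)
        assert [p.kind for p in pts] == ["minimum"]

    def test_plateau_without_sign_change_yields_largest_p(self):
        # all derivatives positive but tiny mid-run: plateau on a rising curve
        a1 = np.array([0.6, 0.05, 0.02, 0.07, 0.6])
        se = np.array([0.05, 0.2, 0.2, 0.2, 0.05])
        tr = make_track(a1, se)
        pts = find_equilibrium_points(tr)
        assert len(pts) == 1
        assert pts[0].track_idx == int(np.argmin(np.abs(a1)))  # largest p = min |a1|/se
        assert pts[0].kind == "maximum"  # left flank positive

    def test_sin_curve_recovers_analytic_extrema(self):
        """Zeros of cos (analytic) are found within one inter-site spacing.

        Sites are a jittered grid (irregular but bounded gaps) and the noise
        is small but nonzero: the CI-zero zone around each crossing must span
        the largest sampling gap for the selection rule to see a site there.
        """
        L, n = 10_000.0, 500
        rng = np.random.default_rng(0)
        pos = np.sort((np.arange(n) + rng.uniform(0, 1, n)) * (L / n))
        d = np.sin(2 * np.pi * pos / L) + rng.normal(0, 0.015, n)
        curve = DifferenceCurve("c", pos, d, np.zeros_like(d), d)
        tr = derivative_track(curve, KernelConfig(h0=400.0, min_influence=30), plan_segments(n, 2000))
        pts = find_equilibrium_points(tr)
        spacing = L / n
        for x_true, kind in ((L / 4, "maximum"), (3 * L / 4, "minimum")):
            near = [p for p in pts if abs(p.pos - x_true) <= L / 8]
            assert len(near) == 1, f"expected one equilibrium near {x_true}"
            assert near[0].kind == kind
            assert abs(near[0].pos - x_true) <= spacing


class TestInvertConfidenceWindow:
    def _pt(self, tr, idx, kind="maximum", l=-0.2, u=0.2):
        return EquilibriumPoint(
            track_idx=idx,
            site_index=idx,
            pos=float(tr.pos[idx]),
            kind=kind,
            deriv=float(tr.alpha1[idx]),
            ci=DerivativeCI(l, u, 0.9),
        )

    def test_hand_traced_scan(self):
        a1 = [0.5, 0.4, 0.3, 0.1, 0.0, -0.1, -0.3, -0.5, -0.6]
        tr = make_track(a1)
        pt = invert_confidence_window(self._pt(tr, 4), tr)
        assert pt.window_method == "inverted"
        # lower: 2 sites left (0.3 >= 0.2); upper: 2 sites right (-0.3 <= -0.2)
        assert pt.window == (tr.pos[2], tr.pos[6])

    def test_mirrored_when_one_side_found(self):
        # flat on the left, resolving on the right after 3 sites
        a1 = [0.05, 0.04, 0.03, 0.02, 0.0, -0.05, -0.1, -0.25, -0.3]
        tr = make_track(a1)
        pt = invert_confidence_window(self._pt(tr, 4), tr)
        assert pt.window_method == "mirrored"
        assert pt.window == (tr.pos[1], tr.pos[7])

    def test_failed_when_flat_both_sides(self):
        tr = make_track([0.01] * 21)
        pt = invert_confidence_window(self._pt(tr, 10), tr)
        assert pt.window_method == "failed" and pt.window is None

    def test_minimum_uses_mirrored_comparisons(self):
        a1 = [-0.5, -0.3, -0.1, 0.0, 0.1, 0.3, 0.5]
        tr = make_track(a1)
        pt = invert_confidence_window(self._pt(tr, 3, kind="minimum"), tr)
        assert pt.window_method == "inverted"
        assert pt.window == (tr.pos[1], tr.pos[5])

    def test_track_edge_counts_as_not_found(self):
        a1 = [0.0, -0.05, -0.1, -0.25, -0.3]  # no left sites at all
        tr = make_track(a1)
        pt = invert_confidence_window(self._pt(tr, 0), tr)
        # right found at 3; mirror 3 left falls off the track -> failed
        assert pt.window_method == "failed"

    def test_window_contains_equilibrium_and_bounded_width(self, rng):
        """Every resolved window contains its point; width <= 20 spacings."""
        for trial in range(20):
            a1 = np.cumsum(rng.normal(0, 0.05, 40))
            tr = make_track(a1, se=np.full(40, 0.08))
            for pt in find_equilibrium_points(tr):
                w = invert_confidence_window(pt, tr)
                if w.window is not None:
                    lo, hi = w.window
                    assert lo <= w.pos <= hi
                    assert hi - lo <= 20 * 100.0


class TestNullCoverage:
    def test_ci_covers_null_derivative_at_nominal_rate(self):
        """On flat-difference binomial data the 95% CIs cover zero ~95%."""
        rng = np.random.default_rng(7)
        n = 1200
        pos = np.cumsum(rng.geometric(1 / 100.0, n)).astype(float)
        depth = rng.poisson(30, (n, 6)) + 1
        meth = rng.binomial(depth, 0.5)
        d = meth[:, :3].sum(1) / depth[:, :3].sum(1) - meth[:, 3:].sum(1) / depth[:, 3:].sum(1)
        curve = DifferenceCurve("c", pos, d, np.zeros(n), d)
        tr = derivative_track(curve, KernelConfig(500.0, min_influence=70), plan_segments(n, 2000))
        cover = tr.ci_zero.mean()
        assert 0.92 <= cover <= 0.99
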