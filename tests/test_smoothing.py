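import numpy as np
import pytest

from cgaim.constraints import ShapeConstraint
from cgaim.smoothing import (
    _calibrate_lambda,
    build_basis,
    fit_constrained_additive,
    normalize_ridge,
    shape_rows,
)


class TestBuildBasis:
    def test_dimensions_and_quantile_knots(self):
        z = np.linspace(0, 1, 101)
        basis = build_basis(z, n_basis=10, degree=3)
        assert basis.n_basis == 10
        interior = basis.knots[4:-4]
        assert interior.size == 6
        assert basis.lo == 0.0 and basis.hi == 1.0

    def test_partition_of_unity(self, rng):
        z = rng.normal(size=300)
        basis = build_basis(z, n_basis=12)
        B = basis.design(np.linspace(z.min(), z.max(), 57))
        assert np.allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            build_basis(np.ones(100), n_basis=10)


class TestShapeRows:
    def test_increasing_first_differences(self):
        basis = build_basis(np.linspace(0, 1, 50), n_basis=4)
        G = shape_rows(basis, ShapeConstraint("increasing"))
        assert np.array_equal(
            G, [[-1, 1, 0, 0], [0, -1, 1, 0], [0, 0, -1, 1]]
        )

    def test_convex_second_differences_up_to_scale(self):
        # with no interior knots the divided-difference rows are
        # proportional to plain second differences
        basis = build_basis(np.linspace(0, 1, 50), n_basis=4)
        G = shape_rows(basis, ShapeConstraint("convex"))
        D2 = np.diff(np.eye(4), n=2, axis=0)
        assert G.shape == (2, 4)
        for g_row, d_row in zip(G, D2):
            ratio = g_row[np.abs(d_row) > 0] / d_row[np.abs(d_row) > 0]
            assert np.allclose(ratio, ratio[0]) and ratio[0] > 0

    def test_combination_stacks(self):
        basis = build_basis(np.linspace(0, 1, 50), n_basis=4)
        G = shape_rows(basis, ShapeConstraint("convex_increasing"))
        assert G.shape == (5, 4)


class TestCalibration:
    def test_target_df_achieved(self, rng):
        z = rng.normal(size=400)
        basis = build_basis(z, n_basis=15)
        B = basis.design(z)
        B -= B.mean(axis=0)
        lam, df = _calibrate_lambda(B, basis.penalty_root(), 10.0)
        assert lam > 0 and abs(df - 10.0) < 1e-4


class TestFitConstrainedAdditive:
    def test_monotone_truth_has_inactive_constraints(self):
        z = np.linspace(-2, 2, 400)
        fit = fit_constrained_additive(z.copy(), [z], ["increasing"])
        assert np.max(np.abs(fit.fitted - z)) < 1e-3
        assert fit.ridge_terms[0].active_shape_rows.size == 0

    def test_isotonic_limit_matches_pava(self, rng):
        # linear spline with a knot at every point and no penalty:
        # the increasing fit is exactly isotonic regression
        from sklearn.isotonic import IsotonicRegression

        z = np.sort(rng.normal(size=60))
        y = -z + rng.normal(size=60)
        fit = fit_constrained_additive(
            y, [z], ["increasing"], target_df=None, n_basis=60, degree=1
        )
        pava = IsotonicRegression().fit_transform(z, y)
        assert np.max(np.abs(fit.fitted - pava)) < 1e-6

    def test_convex_beats_best_linear_fit(self, rng):
        z = rng.uniform(-1, 1, 300)
        y = np.abs(z)
        fit = fit_constrained_additive(y, [z], ["convex"])
        X = np.column_stack([np.ones_like(z), z])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss_lin = float(np.sum((y - X @ beta) ** 2))
        assert fit.rss <= rss_lin + 1e-8

    def test_projection_property(self, rng):
        # constraining never lowers the penalized objective
        z = rng.normal(size=300)
        y = np.sin(2 * z) + 0.2 * rng.normal(size=300)
        free = fit_constrained_additive(y, [z], ["none"])
        con = fit_constrained_additive(y, [z], ["increasing"])
        assert con.rss >= free.rss - 1e-10

    def test_centering_and_exact_decomposition(self, rng):
        z1, z2 = rng.normal(size=300), rng.normal(size=300)
        u = rng.normal(size=300)
        y = np.sin(z1) + z2**2 + 0.5 * u + rng.normal(size=300)
        fit = fit_constrained_additive(
            y, [z1, z2], ["none", "none"], linear_covs=u[:, None]
        )
        assert np.allclose(fit.fitted + fit.residuals, y)
        for t, z in zip(fit.ridge_terms, (z1, z2)):
            assert abs(np.mean(t.term(z))) < 1e-8
        assert np.all(fit.beta >= 0)

    def test_matches_unconstrained_penalized_smoother(self, rng):
        # shapes none, one term: equivalent to a direct penalized
        # normal-equations solve at the same calibrated penalty
        z = rng.normal(size=400)
        y = np.cos(z) + 0.3 * rng.normal(size=400)
        fit = fit_constrained_additive(y, [z], ["none"])
        basis = fit.ridge_terms[0].basis
        B = basis.design(z)
        Bc = B - B.mean(axis=0)
        lam = fit.ridge_terms[0].lam
        P = basis.penalty_root()
        c = np.linalg.solve(Bc.T @ Bc + lam * P.T @ P, Bc.T @ (y - y.mean()))
        oracle = y.mean() + Bc @ c
        assert np.max(np.abs(fit.fitted - oracle)) < 1e-6

    def test_degenerate_term_rejected(self):
        with pytest.raises(ValueError):
            fit_constrained_additive(np.ones(100), [np.ones(100)], ["none"])

    def test_collinear_linear_covariates_rejected(self, rng):
        z = rng.normal(size=100)
        U = np.column_stack([z, 2 * z])
        with pytest.raises(ValueError, match="singular|collinear"):
            fit_constrained_additive(z.copy(), [z], ["none"], linear_covs=U)


class TestNormalizeRidge:
    def test_unit_rms(self, rng):
        v = 2.5 * rng.normal(size=100)
        unit, scale = normalize_ridge(v)
        assert abs(np.sqrt(np.mean(unit**2)) - 1.0) < 1e-12
        assert np.allclose(unit * scale, v)

    def test_null_term(self):
        unit, scale = normalize_ridge(np.zeros(10))
        assert scale == 0.0 and np.all(unit == 0)


class TestRidgeDerivative:
    def test_linear_function_unit_slope(self):
        z = np.linspace(0, 1, 300)
        fit = fit_constrained_additive(z.copy(), [z], ["none"])
        term = fit.ridge_terms[0]
        interior = np.linspace(0.1, 0.9, 50)
        # raw term derivative = beta * g'
        d = fit.beta[0] * term.derivative(interior)
        assert np.max(np.abs(d - 1.0)) < 1e-4

    def test_finite_difference_agreement(self, rng):
        z = rng.normal(size=400)
        y = np.tanh(z) + 0.1 * rng.normal(size=400)
        fit = fit_constrained_additive(y, [z], ["none"])
        term = fit.ridge_terms[0]
        pts = np.linspace(np.quantile(z, 0.1), np.quantile(z, 0.9), 25)
        h = 1e-4
        fd = (term.evaluate(pts + h) - term.evaluate(pts - h)) / (2 * h)
        assert np.max(np.abs(fd - term.derivative(pts))) < 1e-4

    def test_decreasing_shape_derivative_nonpositive(self, rng):
        z = rng.normal(size=300)
        y = -z**3 + rng.normal(size=300)
        fit = fit_constrained_additive(y, [z], ["decreasing"])
        term = fit.ridge_terms[0]
        grid = np.linspace(z.min(), z.max(), 200)
        assert np.all(term.derivative(grid) <= 1e-8)
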