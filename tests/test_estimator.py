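import numpy as np
import pytest

from _oracles import brute_force_qp

from cgaim.constraints import CGAIMSpec, IndexGroup, block_constraints, feasibility
from cgaim.estimator import alpha_qp_step, derivative_matrix, fit_cgaim, init_alpha
from cgaim.synthetic import (
    TRUE_ALPHA,
    SimulationScenario,
    gen_three_index,
    three_index_spec,
)


class TestInitAlpha:
    def _group(self):
        return IndexGroup("g", ["x1", "x2", "x3"], constraints=["nonnegative"])

    def test_exact_linear_recovery(self, rng):
        g = self._group()
        spec = CGAIMSpec(groups=[g])
        X = rng.normal(size=(400, 3))
        a_true = np.array([0.6, 0.3, 0.1])
        y = X @ a_true
        a0 = init_alpha(spec, [X], y)
        assert np.max(np.abs(a0 - a_true / np.linalg.norm(a_true))) < 1e-6

    def test_infeasible_ols_lands_on_boundary(self, rng):
        g = self._group()
        spec = CGAIMSpec(groups=[g])
        X = rng.normal(size=(400, 3))
        y = X @ np.array([1.0, -0.8, 0.2])  # OLS solution violates alpha2 >= 0
        a0 = init_alpha(spec, [X], y)
        ok, active = feasibility(g.C, g.b, a0, tol=1e-7)
        assert ok and active.size >= 1

    def test_random_mode_deterministic(self):
        g = self._group()
        spec = CGAIMSpec(groups=[g], init_mode="random", seed=42)
        X = np.random.default_rng(0).normal(size=(50, 3))
        a1 = init_alpha(spec, [X], X[:, 0])
        a2 = init_alpha(spec, [X], X[:, 0])
        assert np.array_equal(a1, a2)
        assert feasibility(g.C, g.b, a1)[0]


class TestAlphaQPStep:
    def test_zero_residuals_zero_step(self, rng):
        V = rng.normal(size=(50, 3))
        C = np.eye(3)
        delta = alpha_qp_step(V, np.zeros(50), C, np.zeros(3), np.ones(3))
        assert np.max(np.abs(delta)) < 1e-10

    def test_inactive_constraints_gauss_newton(self, rng):
        V = rng.normal(size=(80, 3))
        R = rng.normal(size=80)
        C = np.eye(3)
        alpha_old = np.full(3, 10.0)  # constraints far from active
        delta = alpha_qp_step(V, R, C, np.zeros(3), alpha_old)
        gn = np.linalg.solve(V.T @ V, V.T @ R)
        assert np.max(np.abs(delta - gn)) < 1e-8

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_active_set_oracle(self, seed):
        rng = np.random.default_rng(seed)
        V = rng.normal(size=(40, 2))
        R = rng.normal(size=40) - V @ np.array([1.0, 1.0])
        C = np.eye(2)
        alpha_old = np.array([0.2, 0.1])
        b = np.zeros(2)
        delta = alpha_qp_step(V, R, C, b, alpha_old)
        oracle = brute_force_qp(V, R, C, b, alpha_old)
        assert np.max(np.abs(delta - oracle)) < 1e-8
        assert np.all(C @ (alpha_old + delta) >= -1e-10)

    def test_descent_direction(self, rng):
        V = rng.normal(size=(60, 4))
        R = rng.normal(size=60)
        C = np.eye(4)
        delta = alpha_qp_step(V, R, C, np.zeros(4), np.full(4, 0.5))
        assert R @ V @ delta >= -1e-10


class TestDerivativeMatrix:
    def test_numerical_jacobian(self, noisy_sim, cgaim_spec):
        fit = fit_cgaim(cgaim_spec, noisy_sim["data"])
        data = noisy_sim["data"]
        X_groups = [
            np.column_stack([data[c].to_numpy() for c in g.columns])
            for g in cgaim_spec.groups
        ]
        zs = [fit.index_values[:, j] for j in range(3)]
        V = derivative_matrix(X_groups, fit.additive, zs, [True] * 3)

        def fitted_g_fixed(alpha_stacked):
            out = np.full(fit.n, fit.beta0)
            off = 0
            for j, X in enumerate(X_groups):
                aj = alpha_stacked[off : off + 4]
                off += 4
                out = out + fit.additive.beta[j] * fit.additive.ridge_terms[
                    j
                ].evaluate(X @ aj)
            return out

        a = fit.alpha_vector
        h = 1e-5
        for k in [0, 3, 5, 9]:
            e = np.zeros(12)
            e[k] = h
            fd = (fitted_g_fixed(a + e) - fitted_g_fixed(a - e)) / (2 * h)
            denom = max(np.abs(V[:, k]).max(), 1e-8)
            assert np.max(np.abs(fd - V[:, k])) / denom < 1e-3


class TestFitCGAIM:
    def test_sum_to_one_single_index_recovery(self, rng):
        n = 500
        X = rng.normal(size=(n, 3))
        a_true = np.array([0.6, 0.3, 0.1])
        z = X @ a_true
        y = 1.0 / (1.0 + np.exp(-4 * z))
        g = IndexGroup(
            "g",
            ["x1", "x2", "x3"],
            constraints=["nonnegative"],
            g_shape="increasing",
            identifiability="sum_to_one",
        )
        spec = CGAIMSpec(groups=[g])
        data = {"x1": X[:, 0], "x2": X[:, 1], "x3": X[:, 2], "y": y}
        fit = fit_cgaim(spec, data)
        assert abs(fit.alpha["g"].sum() - 1.0) < 1e-8
        assert np.max(np.abs(fit.alpha["g"] - a_true)) < 0.02

    def test_monotone_rss_trace_and_feasibility(self, noisy_fit, cgaim_spec):
        rss = [t["rss"] for t in noisy_fit.trace]
        assert all(b <= a * (1 + 1e-10) for a, b in zip(rss, rss[1:]))
        C, b = block_constraints(cgaim_spec.groups)
        assert feasibility(C, b, noisy_fit.alpha_vector, tol=1e-7)[0]
        for g in cgaim_spec.groups:
            a = noisy_fit.alpha[g.name]
            assert abs(np.linalg.norm(a) - 1.0) < 1e-8

    def test_determinism(self, noisy_sim, cgaim_spec):
        f1 = fit_cgaim(cgaim_spec, noisy_sim["data"])
        f2 = fit_cgaim(cgaim_spec, noisy_sim["data"])
        assert f1.trace == f2.trace
        assert np.array_equal(f1.alpha_vector, f2.alpha_vector)

    def test_misspecified_constraints_stay_feasible_with_higher_rss(
        self, noiseless_sim
    ):
        data = noiseless_sim["data"]
        good = fit_cgaim(three_index_spec("cgaim"), data)
        spec_m = three_index_spec("mgaim")
        bad = fit_cgaim(spec_m, data)
        C, b = block_constraints(spec_m.groups)
        assert feasibility(C, b, bad.alpha_vector, tol=1e-7)[0]
        assert bad.rss >= good.rss

    def test_noiseless_recovery(self, noiseless_sim, cgaim_spec):
        fit = fit_cgaim(cgaim_spec, noiseless_sim["data"])
        truth = np.concatenate([TRUE_ALPHA[k] for k in ("index1", "index2", "index3")])
        assert np.max(np.abs(fit.alpha_vector - truth)) < 0.02

    def test_nonfinite_data_rejected(self, cgaim_spec, noisy_sim):
        data = noisy_sim["data"].copy()
        data.loc[0, "y"] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_cgaim(cgaim_spec, data)

    def test_normalization_invariance_of_fit(self, rng):
        # rescaling a feasible homogeneous-constraint start leaves the
        # fitted values essentially unchanged (g refit absorbs scale)
        sim = gen_three_index(SimulationScenario(n=400, sigma=0.3, seed=9))
        spec = three_index_spec("cgaim")
        f1 = fit_cgaim(spec, sim["data"])
        a0 = f1.alpha_vector * 3.0  # valid warm start up to scale
        f2 = fit_cgaim(spec, sim["data"], alpha0=a0)
        assert abs(f1.rss - f2.rss) / f1.rss < 1e-3
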