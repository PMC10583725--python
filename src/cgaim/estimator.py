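"""Alternating estimation of the constrained groupwise additive index model.

The fit alternates two steps until the residual sum of squares
stabilizes: (1) at fixed weights, estimate the ridge functions by the
shape-constrained additive smoother; (2) at fixed ridge functions,
update the stacked weight vector alpha by one constrained Gauss-Newton
step, i.e. a quadratic program on the linearized model that keeps
``C alpha >= b``.  A step-halving line search on the full-model RSS
guarantees a monotone objective trace, and each group's weights are
rescaled to the identifiability normalization every iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._qp import solve_lsi
from .constraints import CGAIMSpec, IndexGroup, block_constraints, feasibility
from .smoothing import AdditiveFit, fit_constrained_additive

__all__ = ["CGAIMFit", "init_alpha", "derivative_matrix", "alpha_qp_step", "fit_cgaim"]

logger = logging.getLogger(__name__)

_MAX_HALVINGS = 10
_DELTA_TOL = 1e-8


@dataclass
class CGAIMFit:
    """A fitted CGAIM: weights, additive terms, and model summaries."""

    spec: CGAIMSpec
    alpha: dict[str, np.ndarray]
    additive: AdditiveFit
    index_values: np.ndarray  # n x p matrix of z_ij
    V: np.ndarray
    rss: float
    edf: float
    gcv: float
    trace: list[dict]
    converged: bool
    n: int
    null_groups: list[str] = field(default_factory=list)

    @property
    def alpha_vector(self) -> np.ndarray:
        return np.concatenate([self.alpha[g.name] for g in self.spec.groups])

    @property
    def beta(self) -> np.ndarray:
        return self.additive.beta

    @property
    def beta0(self) -> float:
        return self.additive.beta0

    @property
    def residuals(self) -> np.ndarray:
        return self.additive.residuals

    @property
    def fitted(self) -> np.ndarray:
        return self.additive.fitted

    def group_active(self, group: IndexGroup) -> np.ndarray:
        """Indices of active weight-constraint rows for one group."""
        _, act = feasibility(
            group.C, group.b, self.alpha[group.name], tol=self.spec.active_tol
        )
        return act


def _split(alpha: np.ndarray, groups: list[IndexGroup]) -> list[np.ndarray]:
    out, off = [], 0
    for g in groups:
        out.append(alpha[off : off + g.size])
        off += g.size
    return out


def _positive_rescale(alpha: np.ndarray, groups: list[IndexGroup]) -> np.ndarray:
    """Per-group identifiability rescale by a positive factor only.

    Sign flips are deferred to the end of the fit (a flip with the ridge
    functions held fixed would not preserve the objective).  Groups with
    inhomogeneous bounds (b != 0) are left untouched: rescaling could
    break feasibility, and their constraints already carry the scale.
    """
    parts = []
    for a, g in zip(_split(alpha, groups), groups):
        if not g.homogeneous:
            parts.append(a)
            continue
        if g.identifiability == "sum_to_one":
            s = a.sum()
            parts.append(a / s if s > 1e-12 else a)
        else:
            nrm = np.linalg.norm(a)
            parts.append(a / nrm if nrm > 1e-12 else a)
    return np.concatenate(parts)


def _feasible_point(group: IndexGroup, rng: np.random.Generator) -> np.ndarray:
    """A nonzero feasible weight vector for one group."""
    l = group.size
    for cand in (np.ones(l) / np.sqrt(l), np.ones(l) / l):
        if feasibility(group.C, group.b, cand)[0]:
            return cand
    for _ in range(10000):
        a = rng.standard_normal(l)
        a /= np.linalg.norm(a)
        if group.identifiability == "sum_to_one" and abs(a.sum()) > 1e-8:
            a = a / a.sum()
        for cand in (a, -a):
            if feasibility(group.C, group.b, cand)[0]:
                return cand
    raise RuntimeError(
        f"could not sample a feasible start for group {group.name!r}; "
        "try init_mode='regression'"
    )


def init_alpha(
    spec: CGAIMSpec,
    X_groups: list[np.ndarray],
    y: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Initial stacked weight vector.

    ``regression`` mode solves the constrained linear regression of the
    pooled predictors on the response (the alpha-update QP with the
    design matrix in place of the Jacobian); ``random`` mode rejection-
    samples unit vectors until each group is feasible.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if spec.init_mode == "random":
        alpha = np.concatenate([_feasible_point(g, rng) for g in spec.groups])
        return _positive_rescale(alpha, spec.groups)
    X = np.hstack(X_groups)
    n, ptot = X.shape
    if n <= ptot:
        raise ValueError("regression initialization needs n > total predictors")
    C, b = block_constraints(spec.groups)
    Xc = X - X.mean(axis=0)
    yc = np.asarray(y, dtype=float) - float(np.mean(y))
    alpha = solve_lsi(Xc, yc, C if C.shape[0] else None, b, ridge=1e-10)
    # degenerate (all-zero) groups fall back to a feasible point
    parts = []
    for a, g in zip(_split(alpha, spec.groups), spec.groups):
        if np.linalg.norm(a) < 1e-10:
            a = _feasible_point(g, rng)
        parts.append(a)
    return _positive_rescale(np.concatenate(parts), spec.groups)


def derivative_matrix(
    X_groups: list[np.ndarray],
    additive: AdditiveFit,
    zs: list[np.ndarray],
    active: list[bool],
) -> np.ndarray:
    """Jacobian of the fitted model with respect to the stacked weights.

    Row i concatenates ``x_ij * beta_j * g_j'(z_ij)`` across groups;
    columns of inactive (null) groups are zero.
    """
    cols = []
    it = iter(range(len(additive.ridge_terms)))
    for X, z, on in zip(X_groups, zs, active):
        if not on:
            cols.append(np.zeros_like(X))
            continue
        t = next(it)
        rf = additive.ridge_terms[t]
        # beta_j * g_j' equals the raw term derivative
        d = additive.beta[t] * rf.derivative(z)
        cols.append(X * d[:, None])
    return np.hstack(cols)


def alpha_qp_step(
    V: np.ndarray,
    R: np.ndarray,
    C: np.ndarray,
    b: np.ndarray,
    alpha_old: np.ndarray,
) -> np.ndarray:
    """One constrained Gauss-Newton update: min ||R - V d|| s.t. C(a+d) >= b."""
    h = b - C @ alpha_old if C.shape[0] else None
    G = C if C.shape[0] else None
    try:
        delta = solve_lsi(V, R, G, h)
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        logger.warning("singular V'V in alpha step; adding ridge jitter")
        delta = solve_lsi(V, R, G, h, ridge=1e-10)
    return delta


def fit_cgaim(
    spec: CGAIMSpec,
    data,
    response: str = "y",
    alpha0: np.ndarray | None = None,
    max_iter: int | None = None,
) -> CGAIMFit:
    """Fit the CGAIM on column-addressable ``data`` (DataFrame or dict).

    ``alpha0`` warm-starts the weights (used by the bootstrap); the
    identifiability normalization, edf and GCV are finalized on exit.
    """
    y = np.asarray(data[response], dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in the response")
    n = y.shape[0]
    groups = spec.groups
    X_groups = []
    for g in groups:
        X = np.column_stack([np.asarray(data[c], dtype=float) for c in g.columns])
        if not np.all(np.isfinite(X)):
            raise ValueError(f"non-finite values in group {g.name!r}")
        X_groups.append(X)
    smooth_covs, linear_cols = [], []
    for cov in spec.covariates:
        w = np.asarray(data[cov.name], dtype=float)
        if cov.mode == "smooth":
            smooth_covs.append((w, cov.f_shape))
        else:
            linear_cols.append(w)
    U = np.column_stack(linear_cols) if linear_cols else None

    C, b = block_constraints(groups)
    rng = np.random.default_rng(spec.seed)

    shapes = [g.g_shape for g in groups]

    def additive_at(a: np.ndarray):
        zs = [X @ aj for X, aj in zip(X_groups, _split(a, groups))]
        act = [np.ptp(z) > 1e-10 for z in zs]
        fit = fit_constrained_additive(
            y,
            [z for z, on in zip(zs, act) if on],
            [s for s, on in zip(shapes, act) if on],
            smooth_covs=smooth_covs,
            linear_covs=U,
            target_df=spec.target_df,
            n_basis=spec.n_basis,
            select_df=spec.smooth_select == "gcv",
        )
        return fit, zs, act

    if alpha0 is not None:
        alpha = _positive_rescale(np.asarray(alpha0, dtype=float).copy(), groups)
        fit, zs, act = additive_at(alpha)
    else:
        # the regression start can land in a corner of the cone when a
        # ridge is nearly even (its linear projection points against the
        # constraints); evaluate a few deterministic feasible starts and
        # keep the one with the lowest initial objective
        candidates = [init_alpha(spec, X_groups, y, rng)]
        if spec.init_mode == "regression":
            candidates.append(init_alpha(spec, X_groups, -y, rng))
            try:
                candidates.append(
                    _positive_rescale(
                        np.concatenate(
                            [_feasible_point(g, rng) for g in groups]
                        ),
                        groups,
                    )
                )
            except RuntimeError:
                pass
        best = None
        for cand in candidates:
            try:
                trial = additive_at(cand)
            except ValueError:
                continue
            if best is None or trial[0].rss < best[1][0].rss:
                best = cand, trial
        if best is None:
            raise RuntimeError("no feasible starting point produced a valid fit")
        alpha, (fit, zs, act) = best
    if C.shape[0] and not feasibility(C, b, alpha, tol=1e-6)[0]:
        raise ValueError("initial weights violate the constraints")
    rss = fit.rss
    trace = [{"rss": rss, "step_norm": 0.0}]
    converged = False
    n_iter = spec.max_iter if max_iter is None else max_iter

    for _ in range(n_iter):
        V = derivative_matrix(X_groups, fit, zs, act)
        delta = alpha_qp_step(V, fit.residuals, C, b, alpha)
        step = float(np.linalg.norm(delta))
        if step < _DELTA_TOL * (1.0 + np.linalg.norm(alpha)):
            converged = True
            break
        t, accepted = 1.0, False
        for _h in range(_MAX_HALVINGS + 1):
            cand = _positive_rescale(alpha + t * delta, groups)
            if C.shape[0] and not feasibility(C, b, cand, tol=1e-7)[0]:
                t *= 0.5
                continue
            fit_c, zs_c, act_c = additive_at(cand)
            if fit_c.rss <= rss * (1.0 + 1e-12):
                accepted = True
                break
            t *= 0.5
        if not accepted:
            converged = True  # no feasible descent step left
            break
        alpha, fit, zs, act = cand, fit_c, zs_c, act_c
        new_rss = fit_c.rss
        trace.append({"rss": new_rss, "step_norm": t * step})
        if rss - new_rss <= spec.tol * max(rss, 1e-300):
            rss = new_rss
            converged = True
            break
        rss = new_rss

    # final identifiability normalization (may flip signs for groups whose
    # constraints permit it); the ridge functions are refit once to absorb it
    final = np.concatenate(
        [g.normalize(a) for a, g in zip(_split(alpha, groups), groups)]
    )
    if not np.allclose(final, alpha):
        alpha = final
        fit, zs, act = additive_at(alpha)
    rss = fit.rss
    V = derivative_matrix(X_groups, fit, zs, act)

    from .selection import edf_total, gcv as gcv_fn

    result = CGAIMFit(
        spec=spec,
        alpha={g.name: a for g, a in zip(groups, _split(alpha, groups))},
        additive=fit,
        index_values=np.column_stack(zs),
        V=V,
        rss=rss,
        edf=0.0,
        gcv=0.0,
        trace=trace,
        converged=converged,
        n=n,
        null_groups=[g.name for g, on in zip(groups, act) if not on],
    )
    result.edf = edf_total(result)
    result.gcv = gcv_fn(rss, n, result.edf)
    return result
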