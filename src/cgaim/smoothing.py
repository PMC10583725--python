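"""Shape-constrained penalized B-spline additive smoother.

This is step 1 of the alternating estimation algorithm: with the index
weights held fixed, the ridge functions g_j (and any smooth covariate
functions f_k) are estimated jointly by penalized least squares with
linear inequality rows on the spline coefficients enforcing the
requested shapes.  Monotonicity is imposed through first differences of
the coefficients and curvature through differences of the derivative
spline coefficients (divided differences with knot-gap weights), both
sufficient conditions for B-spline curves on arbitrary knots.

Smoothness is fixed by default: the penalty weight of each term is
calibrated by root finding so that the *unconstrained* smoother trace
for that term equals ``target_df`` (default 10 equivalent degrees of
freedom).  Unconstrained terms can instead have their penalty selected
by per-term GCV on partial residuals (``select_df=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.interpolate import BSpline
from scipy.optimize import brentq

from ._qp import solve_lsi
from .constraints import ShapeConstraint

__all__ = [
    "SplineBasis",
    "RidgeFunction",
    "AdditiveFit",
    "build_basis",
    "shape_rows",
    "fit_constrained_additive",
    "normalize_ridge",
]

_RIDGE_JITTER = 1e-9  # rank-safety ridge on the stacked design


@dataclass(frozen=True)
class SplineBasis:
    """B-spline basis with quantile interior knots on a data range."""

    knots: np.ndarray  # full (augmented) knot vector
    degree: int
    n_basis: int
    penalty_order: int = 2

    @property
    def lo(self) -> float:
        return float(self.knots[self.degree])

    @property
    def hi(self) -> float:
        return float(self.knots[-self.degree - 1])

    def design(self, z: np.ndarray) -> np.ndarray:
        zc = np.clip(np.asarray(z, dtype=float), self.lo, self.hi)
        return BSpline.design_matrix(
            zc, self.knots, self.degree, extrapolate=False
        ).toarray()

    def penalty_root(self) -> np.ndarray:
        """Operator D such that the penalty is ||D c||^2.

        For the default order 2 this is the knot-aware divided
        difference (differences of the derivative-spline coefficients),
        which leaves linear functions unpenalized on arbitrary knots;
        plain differences are used for other orders.
        """
        nb, k, t = self.n_basis, self.degree, self.knots
        if self.penalty_order != 2 or k < 1:
            return np.diff(np.eye(nb), n=self.penalty_order, axis=0)
        D1 = np.diff(np.eye(nb), axis=0)
        gaps = t[1 + k : nb + k] - t[1:nb]
        return np.diff((k / gaps)[:, None] * D1, axis=0)


def build_basis(
    z: np.ndarray, n_basis: int = 15, degree: int = 3, penalty_order: int = 2
) -> SplineBasis:
    """Quantile-knot basis covering the range of ``z``."""
    z = np.asarray(z, dtype=float)
    uniq = np.unique(z)
    if uniq.size < n_basis:
        raise ValueError(
            f"need >= {n_basis} distinct values to build the basis, "
            f"got {uniq.size}"
        )
    n_interior = n_basis - degree - 1
    lo, hi = uniq[0], uniq[-1]
    if n_interior > 0:
        probs = np.arange(1, n_interior + 1) / (n_interior + 1)
        interior = np.quantile(uniq, probs)
        interior = interior[(interior > lo) & (interior < hi)]
        # ties in quantiles would create zero-support basis functions
        interior = np.unique(interior)
        if interior.size < n_interior:
            raise ValueError("too many tied values for the requested basis")
    else:
        interior = np.zeros(0)
    knots = np.concatenate(
        [np.full(degree + 1, lo), interior, np.full(degree + 1, hi)]
    )
    return SplineBasis(knots, degree, n_basis, penalty_order)


def shape_rows(basis: SplineBasis, shape: ShapeConstraint) -> np.ndarray:
    """Inequality rows G with G c >= 0 enforcing ``shape`` on the spline.

    Monotone: signed first differences of coefficients.  Curvature:
    signed differences of the derivative-spline coefficients
    ``d_i = k (c_{i+1} - c_i) / (t_{i+k+1} - t_{i+1})`` (equal to plain
    second differences up to scale when knot gaps are equal).
    """
    if isinstance(shape, str):
        shape = ShapeConstraint(shape)
    nb, k, t = basis.n_basis, basis.degree, basis.knots
    rows = []
    D1 = np.diff(np.eye(nb), axis=0)
    if shape.monotone is not None:
        rows.append(D1 if shape.monotone == "increasing" else -D1)
    if shape.curvature is not None:
        gaps = t[1 + k : nb + k] - t[1:nb]  # support of each derivative coef
        Dd = np.diff((k / gaps)[:, None] * D1, axis=0)
        rows.append(Dd if shape.curvature == "convex" else -Dd)
    if not rows:
        return np.zeros((0, nb))
    return np.vstack(rows)


def _term_eig(B: np.ndarray, P_root: np.ndarray):
    """Generalized eigensystem of (penalty, B'B) for fast df/GCV scans.

    Returns (gamma, V) with V'(B'B)V = I and V'PV = diag(gamma), so the
    term smoother trace is sum 1/(1 + lam*gamma) and ridge coefficients
    at penalty lam are V (I + lam*Gamma)^-1 V' B'r.
    """
    M = B.T @ B
    M = M + (1e-10 * np.trace(M) / M.shape[0] + 1e-12) * np.eye(M.shape[0])
    P = P_root.T @ P_root
    gamma, V = linalg.eigh(P, M)
    return np.clip(gamma, 0.0, None), V


def _calibrate_lambda(
    B: np.ndarray, P_root: np.ndarray, target_df: float
) -> tuple[float, float]:
    """Penalty weight such that tr of the term's hat matrix = target_df."""
    M = B.T @ B
    M = M + (1e-10 * np.trace(M) / M.shape[0] + 1e-12) * np.eye(M.shape[0])
    P = P_root.T @ P_root
    gamma = np.clip(linalg.eigh(P, M, eigvals_only=True), 0.0, None)

    def df(lam: float) -> float:
        return float(np.sum(1.0 / (1.0 + lam * gamma)))

    if df(0.0) <= target_df:
        return 0.0, df(0.0)
    lo, hi = 1e-9, 1e13
    if df(hi) >= target_df:  # cannot smooth below target; saturate
        return hi, df(hi)
    loglam = brentq(
        lambda t: df(10.0**t) - target_df, np.log10(lo), np.log10(hi), xtol=1e-8
    )
    lam = 10.0**loglam
    return lam, df(lam)


def _gcv_lambda(
    B: np.ndarray, P_root: np.ndarray, r: np.ndarray, n: int
) -> tuple[float, float]:
    """Penalty weight minimizing the single-term GCV on partial residuals.

    Scans a log-spaced grid; the residual sum of squares and trace at
    each lambda come from the generalized eigensystem in O(n_basis).
    """
    gamma, V = _term_eig(B, P_root)
    d = V.T @ (B.T @ r)
    rr = float(r @ r)
    grid = np.concatenate([[0.0], np.logspace(-9, 13, 45)])
    best = (np.inf, 0.0, float(B.shape[1]))
    for lam in grid:
        shrink = 1.0 / (1.0 + lam * gamma)
        df = float(np.sum(shrink))
        if df >= n:
            continue
        rss = rr - 2.0 * float(d**2 @ shrink) + float(d**2 @ shrink**2)
        score = (rss / n) / (1.0 - df / n) ** 2
        if score < best[0]:
            best = (score, lam, df)
    return best[1], best[2]


def _face_edf(
    M: np.ndarray,
    P_root: np.ndarray,
    lam: float,
    active_rows: np.ndarray | None,
) -> float:
    """Stein degrees of freedom of a cone-constrained penalized smoother.

    Almost everywhere, the constrained fit is the linear penalized
    smoother restricted to the face of the cone where the active
    constraints hold with equality, so its divergence (= df) is the
    trace of that face-restricted hat matrix (M is the term's Gram
    matrix B'B).  With no active rows this is the ordinary penalized
    trace.
    """
    P = lam * (P_root.T @ P_root)
    nb = M.shape[0]
    if active_rows is None or active_rows.size == 0:
        Z = np.eye(nb)
    else:
        Z = linalg.null_space(np.atleast_2d(active_rows))
        if Z.size == 0:
            return 0.0
    Mz = Z.T @ M @ Z
    Az = Mz + Z.T @ P @ Z
    Az = Az + 1e-10 * np.trace(Az) / Az.shape[0] * np.eye(Az.shape[0])
    return float(np.trace(np.linalg.solve(Az, Mz)))


@dataclass
class RidgeFunction:
    """A fitted (possibly shape-constrained) spline term, unit RMS norm.

    ``evaluate`` returns the normalized function g; the raw fitted term
    is ``scale * g``.  Outside the basis range the curve is extended
    linearly with the boundary derivative.
    """

    basis: SplineBasis
    coef: np.ndarray
    center: float
    scale: float
    shape: ShapeConstraint
    edf_unconstrained: float = 0.0
    active_shape_rows: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    lam: float = 0.0
    gram: np.ndarray | None = None  # centered-basis Gram matrix, for edf
    null: bool = False

    @property
    def active_shape_rank(self) -> int:
        """Rank of the active shape-constraint rows (face codimension)."""
        if "_asr" not in self.__dict__:
            rows = shape_rows(self.basis, self.shape)[self.active_shape_rows]
            self.__dict__["_asr"] = (
                int(np.linalg.matrix_rank(rows)) if rows.size else 0
            )
        return self.__dict__["_asr"]

    @property
    def edf_face(self) -> float:
        """Face-restricted penalized hat trace (Stein df) of this term."""
        if "_edf_face" not in self.__dict__:
            act = shape_rows(self.basis, self.shape)[self.active_shape_rows]
            self.__dict__["_edf_face"] = _face_edf(
                self.gram, self.basis.penalty_root(), self.lam,
                act if act.size else None,
            )
        return self.__dict__["_edf_face"]

    def _spline(self) -> BSpline:
        return BSpline(self.basis.knots, self.coef, self.basis.degree)

    def _raw(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        lo, hi = self.basis.lo, self.basis.hi
        zc = np.clip(z, lo, hi)
        s = self._spline()
        out = s(zc)
        below, above = z < lo, z > hi
        if below.any() or above.any():
            ds = s.derivative()
            out = np.where(below, s(lo) + ds(lo) * (z - lo), out)
            out = np.where(above, s(hi) + ds(hi) * (z - hi), out)
        return out

    def evaluate(self, z: np.ndarray) -> np.ndarray:
        if self.null:
            return np.zeros(np.asarray(z, dtype=float).shape)
        return (self._raw(z) - self.center) / self.scale

    __call__ = evaluate

    def derivative(self, z: np.ndarray) -> np.ndarray:
        """g'(z); constant (boundary) slope beyond the basis range."""
        if self.null:
            return np.zeros(np.asarray(z, dtype=float).shape)
        z = np.asarray(z, dtype=float)
        zc = np.clip(z, self.basis.lo, self.basis.hi)
        return self._spline().derivative()(zc) / self.scale

    def term(self, z: np.ndarray) -> np.ndarray:
        """The raw additive contribution scale * g(z)."""
        return (self._raw(z) - self.center) if not self.null else np.zeros(
            np.asarray(z, dtype=float).shape
        )


def normalize_ridge(
    values: np.ndarray, tol: float = 1e-12
) -> tuple[np.ndarray, float]:
    """Scale fitted term values to unit RMS; return (unit values, scale)."""
    values = np.asarray(values, dtype=float)
    scale = float(np.sqrt(np.mean(values**2)))
    if scale < tol:
        return np.zeros_like(values), 0.0
    return values / scale, scale


@dataclass
class AdditiveFit:
    """Joint fit of all ridge and covariate terms at fixed index weights."""

    ridge_terms: list[RidgeFunction]
    covariate_terms: list[RidgeFunction]
    beta0: float
    beta: np.ndarray
    gamma: np.ndarray
    theta: np.ndarray
    u_means: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)


def fit_constrained_additive(
    y: np.ndarray,
    indices: list[np.ndarray],
    shapes: list[ShapeConstraint | str],
    smooth_covs: list[tuple[np.ndarray, ShapeConstraint | str]] | None = None,
    linear_covs: np.ndarray | None = None,
    target_df: float | None = 10.0,
    n_basis: int = 15,
    degree: int = 3,
    active_tol: float = 1e-7,
    select_df: bool = False,
) -> AdditiveFit:
    """Fit the shape-constrained additive model at fixed index values.

    Minimizes the penalized residual sum of squares over all spline
    coefficient blocks and linear-covariate coefficients jointly,
    subject to per-term shape rows.  All term bases are column-centered
    so every fitted term has exact zero sample mean and the intercept
    absorbs the level.  ``target_df=None`` drops the penalty entirely
    (interpolating limit, used mainly for oracle checks).

    With ``select_df=True`` the penalty of each *unconstrained* (shape
    ``none``) term is chosen by single-term GCV on its partial residuals
    (two backfitting passes) instead of the fixed ``target_df``
    calibration; shape-constrained terms always use the fixed target.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    smooth_covs = smooth_covs or []
    terms: list[tuple[np.ndarray, ShapeConstraint]] = []
    for z, sh in list(zip(indices, shapes)) + list(smooth_covs):
        if isinstance(sh, str):
            sh = ShapeConstraint(sh)
        z = np.asarray(z, dtype=float)
        if z.shape[0] != n:
            raise ValueError("all term vectors must have length n")
        if np.ptp(z) < 1e-12:
            raise ValueError("constant index/covariate values: degenerate term")
        terms.append((z, sh))

    bases, blocks, means, proots, shape_blocks, lams, dfs = (
        [], [], [], [], [], [], [],
    )
    for z, sh in terms:
        basis = build_basis(z, n_basis=n_basis, degree=degree)
        B = basis.design(z)
        m = B.mean(axis=0)
        Bc = B - m
        Proot = basis.penalty_root()
        if target_df is None:
            lam, df_u = 0.0, float(basis.n_basis)
        else:
            lam, df_u = _calibrate_lambda(Bc, Proot, target_df)
        bases.append(basis)
        blocks.append(Bc)
        means.append(m)
        proots.append(Proot)
        shape_blocks.append(shape_rows(basis, sh))
        lams.append(lam)
        dfs.append(df_u)

    if linear_covs is not None:
        U = np.atleast_2d(np.asarray(linear_covs, dtype=float))
        if U.shape[0] != n:
            U = U.T
        u_means = U.mean(axis=0)
        Uc = U - u_means
        if np.linalg.matrix_rank(Uc) < Uc.shape[1]:
            raise ValueError("collinear linear covariates: singular design")
    else:
        Uc = np.zeros((n, 0))
        u_means = np.zeros(0)

    ybar = float(y.mean())
    yc = y - ybar
    A = np.hstack(blocks + [Uc]) if blocks else Uc
    sizes = [b.shape[1] for b in blocks] + [Uc.shape[1]]
    total = sum(sizes)

    def _solve(cur_lams: list[float]) -> np.ndarray:
        # stacked penalty rows, block-diagonal over terms, zero on U columns
        pen_rows = []
        off = 0
        for Bc, Pr, lam in zip(blocks, proots, cur_lams):
            if lam > 0.0:
                block = np.zeros((Pr.shape[0], total))
                block[:, off : off + Pr.shape[1]] = np.sqrt(lam) * Pr
                pen_rows.append(block)
            off += Bc.shape[1]
        A_aug = np.vstack([A] + pen_rows) if pen_rows else A
        y_aug = np.concatenate([yc, np.zeros(A_aug.shape[0] - n)])
        return solve_lsi(A_aug, y_aug, G, ridge=_RIDGE_JITTER)

    g_rows = []
    off = 0
    for Bc, Sr in zip(blocks, shape_blocks):
        if Sr.shape[0]:
            block = np.zeros((Sr.shape[0], total))
            block[:, off : off + Sr.shape[1]] = Sr
            g_rows.append(block)
        off += Bc.shape[1]
    G = np.vstack(g_rows) if g_rows else None

    coef = _solve(lams)
    if select_df and target_df is not None:
        adaptive = [i for i, (_, sh) in enumerate(terms) if sh.kind == "none"]
        for _pass in range(2 if adaptive else 0):
            fit_all = A @ coef
            off_list = np.cumsum([0] + sizes)
            for i in adaptive:
                ci = coef[off_list[i] : off_list[i + 1]]
                partial = yc - fit_all + blocks[i] @ ci
                lams[i], dfs[i] = _gcv_lambda(blocks[i], proots[i], partial, n)
            coef = _solve(lams)

    ridge_terms: list[RidgeFunction] = []
    cov_terms: list[RidgeFunction] = []
    scales = []
    fitted = np.full(n, ybar)
    off = 0
    for i, ((z, sh), basis, Bc, m, df_u, Sr) in enumerate(
        zip(terms, bases, blocks, means, dfs, shape_blocks)
    ):
        c = coef[off : off + basis.n_basis]
        off += basis.n_basis
        vals = Bc @ c
        _, scale = normalize_ridge(vals)
        if Sr.shape[0]:
            slack = np.abs(Sr @ c)
            act = np.flatnonzero(slack <= active_tol * max(1.0, np.abs(c).max()))
        else:
            act = np.zeros(0, dtype=int)
        rf = RidgeFunction(
            basis=basis,
            coef=c,
            center=float(m @ c),
            scale=scale if scale > 0 else 1.0,
            shape=sh,
            edf_unconstrained=df_u,
            active_shape_rows=act,
            lam=lams[i],
            gram=Bc.T @ Bc,
            null=scale == 0.0,
        )
        scales.append(scale)
        fitted = fitted + vals
        (ridge_terms if i < len(indices) else cov_terms).append(rf)

    theta = coef[off:]
    fitted = fitted + Uc @ theta
    residuals = y - fitted
    return AdditiveFit(
        ridge_terms=ridge_terms,
        covariate_terms=cov_terms,
        beta0=ybar,
        beta=np.asarray(scales[: len(indices)]),
        gamma=np.asarray(scales[len(indices) :]),
        theta=theta,
        u_means=u_means,
        fitted=fitted,
        residuals=residuals,
    )
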