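"""Inequality-constrained least squares.

Solves  min_x ||A x - y||^2  subject to  G x >= h  by the classical
LSI -> LDP -> NNLS reduction of Lawson & Hanson (1974, ch. 23).  All
quadratic programs in the package (shape-constrained smoothing, the
index-weight update, constrained initialization) are least-squares
problems of this form, so one solver serves them all.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from scipy.optimize import nnls

__all__ = ["solve_lsi", "InfeasibleError"]


class InfeasibleError(RuntimeError):
    """The constraint system G x >= h has no solution."""


def _solve_ldp(G: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Least distance programming: min ||z|| s.t. G z >= h."""
    m, nvar = G.shape
    if m == 0:
        return np.zeros(nvar)
    E = np.vstack([G.T, h[np.newaxis, :]])  # (nvar+1) x m
    f = np.zeros(nvar + 1)
    f[-1] = 1.0
    u, _ = nnls(E, f, maxiter=max(30 * m, 300))
    r = E @ u - f
    if abs(r[-1]) < 1e-12:
        raise InfeasibleError("inequality constraints are infeasible")
    return -r[:-1] / r[-1]


def solve_lsi(
    A: np.ndarray,
    y: np.ndarray,
    G: np.ndarray | None = None,
    h: np.ndarray | None = None,
    *,
    ridge: float = 0.0,
) -> np.ndarray:
    """Minimize ||A x - y||^2 (+ ridge ||x||^2) subject to G x >= h.

    A must have full column rank (a small ``ridge`` can be passed to
    guarantee it).  With no constraints this is ordinary least squares.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = A.shape
    if ridge > 0.0:
        A = np.vstack([A, np.sqrt(ridge) * np.eye(p)])
        y = np.concatenate([y, np.zeros(p)])
    if G is None or G.shape[0] == 0:
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        return x
    G = np.asarray(G, dtype=float)
    h = np.zeros(G.shape[0]) if h is None else np.asarray(h, dtype=float)
    if G.shape[1] != p or h.shape[0] != G.shape[0]:
        raise ValueError("constraint dimensions do not conform with A")
    # Cholesky of the Gram matrix gives the same triangular factor as a
    # QR of A (up to row signs) at a fraction of the cost for tall A
    try:
        R = linalg.cholesky(A.T @ A, lower=False)
    except linalg.LinAlgError:
        return solve_lsi(A, y, G, h, ridge=max(ridge * 10.0, 1e-10))
    diag = np.abs(np.diag(R))
    if diag.min() < 1e-10 * max(diag.max(), 1.0):
        # rank-deficient design: retry with jitter so R is invertible
        return solve_lsi(A, y, G, h, ridge=max(ridge * 10.0, 1e-10))
    Qty = linalg.solve_triangular(R, A.T @ y, trans="T", lower=False)
    Gt = linalg.solve_triangular(R, G.T, trans="T", lower=False).T
    ht = h - Gt @ Qty
    z = _solve_ldp(Gt, ht)
    return linalg.solve_triangular(R, z + Qty, lower=False)
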