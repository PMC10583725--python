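"""Uncertainty quantification for the index weights.

Two routes are offered.  The *normal approximation* treats the fit as a
constrained nonlinear least-squares problem: the unconstrained
covariance is ``Sigma_alpha = s^2 (V'V)^{-1}`` with ``s^2`` based on the
model edf, and the constrained sampling distribution of the transformed
vector ``xi = C (alpha - alpha_hat)`` is a multivariate normal with
covariance ``C Sigma_alpha C'`` truncated below at ``b - C alpha_hat``
(after augmenting C to a square invertible matrix with never-active
rows).  The *residual bootstrap* resamples fitted-model residuals onto
the fitted values and refits the whole model, warm-started at the
estimate.  Confidence intervals are empirical percentiles either way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

from .constraints import NEG_INF_BOUND, augment_constraints, block_constraints
from .estimator import CGAIMFit, fit_cgaim

__all__ = [
    "InferenceResult",
    "alpha_covariance",
    "truncated_normal_samples",
    "normal_inference",
    "residual_bootstrap",
    "percentile_ci",
]

logger = logging.getLogger(__name__)


@dataclass
class InferenceResult:
    method: str
    samples: np.ndarray  # B x total-weights
    ci: np.ndarray  # total-weights x 2
    level: float
    B: int
    sigma2_hat: float | None = None
    Sigma_alpha: np.ndarray | None = None
    n_failed: int = 0
    beta_samples: np.ndarray | None = None
    curve_grid: np.ndarray | None = None
    curve_samples: list[np.ndarray] | None = None

    def to_frame(self, names: list[str], estimate: np.ndarray):
        import pandas as pd

        return pd.DataFrame(
            {
                "coefficient": names,
                "estimate": estimate,
                "lower": self.ci[:, 0],
                "upper": self.ci[:, 1],
                "method": self.method,
            }
        )


def alpha_covariance(
    V: np.ndarray, rss: float, n: int, edf: float
) -> tuple[np.ndarray, float]:
    """Unconstrained covariance s^2 (V'V)^{-1} of the stacked weights."""
    if edf >= n:
        raise ValueError("edf must be below n")
    s2 = rss / (n - edf)
    M = V.T @ V
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "V'V is numerically singular; use the residual bootstrap"
        )
    Sigma = s2 * np.linalg.inv(M)
    return 0.5 * (Sigma + Sigma.T), float(s2)


def _sample_lower_truncated_std_normal(
    a: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw X ~ N(0,1) conditional on X >= a, elementwise (vectorized)."""
    u = rng.uniform(size=a.shape)
    tail = ndtr(-a)  # P(X >= a)
    safe = tail > 1e-300
    # inverse-CDF on the upper tail: survival value uniform on (0, tail]
    s = np.clip(np.where(safe, u * tail, 0.5), 1e-320, 1.0 - 1e-16)
    x = -ndtri(s)
    # deep truncation: exponential proposal around the boundary
    deep = ~safe
    if deep.any():
        ad = np.clip(a[deep], 1.0, None)
        x[deep] = ad + rng.exponential(1.0 / ad)
    return x


def truncated_normal_samples(
    alpha_hat: np.ndarray,
    Sigma_alpha: np.ndarray,
    C: np.ndarray,
    b: np.ndarray,
    B: int,
    seed: int | np.random.Generator = 0,
    burn_in: int = 100,
) -> np.ndarray:
    """Sample weight vectors from the truncated-normal approximation.

    Runs ``B`` parallel Gibbs chains on the transformed vector xi with
    covariance ``C Sigma_alpha C'`` and lower bound ``b - C alpha_hat``
    (rows at the -inf sentinel are unbounded), then back-transforms
    ``alpha* = alpha_hat + C^{-1} xi``.  Every returned row is feasible.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    C = np.asarray(C, dtype=float)
    L = C.shape[0]
    if C.shape[0] != C.shape[1]:
        raise ValueError("C must be square; augment the constraint system first")
    Sigma_xi = C @ Sigma_alpha @ C.T
    Sigma_xi = 0.5 * (Sigma_xi + Sigma_xi.T)
    lower = np.asarray(b, dtype=float) - C @ alpha_hat
    Lam = np.linalg.inv(Sigma_xi + 1e-12 * np.trace(Sigma_xi) / L * np.eye(L))
    cond_sd = 1.0 / np.sqrt(np.diag(Lam))
    xi = np.tile(np.maximum(lower, 0.0), (B, 1))
    for _ in range(burn_in):
        for i in range(L):
            mu = -(xi @ Lam[:, i] - xi[:, i] * Lam[i, i]) / Lam[i, i]
            if lower[i] <= NEG_INF_BOUND:
                xi[:, i] = mu + cond_sd[i] * rng.standard_normal(B)
            else:
                a = (lower[i] - mu) / cond_sd[i]
                xi[:, i] = mu + cond_sd[i] * _sample_lower_truncated_std_normal(
                    a, rng
                )
    return alpha_hat + xi @ np.linalg.inv(C).T


def _sample_interval_std_normal(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """X ~ N(0,1) conditional on a <= X <= b, elementwise and tail-stable."""
    flip = a + b > 0  # work in the negative tail where ndtri is stable
    lo = np.where(flip, -b, a)
    hi = np.where(flip, -a, b)
    p_lo = ndtr(lo)
    p_hi = ndtr(hi)
    u = p_lo + rng.uniform(size=a.shape) * np.maximum(p_hi - p_lo, 1e-320)
    x = ndtri(np.clip(u, 1e-320, 1.0 - 1e-16))
    x = np.clip(x, lo, hi)
    return np.where(flip, -x, x)


def _gibbs_polyhedral(
    alpha_hat: np.ndarray,
    Sigma_alpha: np.ndarray,
    C: np.ndarray,
    b: np.ndarray,
    B: int,
    rng: np.random.Generator,
    burn_in: int = 100,
) -> np.ndarray:
    """Gibbs sampling of N(alpha_hat, Sigma) truncated to {C alpha >= b}.

    Works for any number of constraint rows (the square-C transform of
    ``truncated_normal_samples`` is undefined when rows exceed columns).
    Coordinates are updated in place over B parallel chains started at
    the (feasible) estimate.
    """
    L = alpha_hat.shape[0]
    Lam = np.linalg.inv(
        Sigma_alpha + 1e-12 * np.trace(Sigma_alpha) / L * np.eye(L)
    )
    cond_sd = 1.0 / np.sqrt(np.diag(Lam))
    eta = np.zeros((B, L))  # alpha - alpha_hat
    t0 = b - C @ alpha_hat  # row slacks at the estimate (<= 0)
    for _ in range(burn_in):
        for i in range(L):
            mu = -(eta @ Lam[:, i] - eta[:, i] * Lam[i, i]) / Lam[i, i]
            resid = t0[None, :] - eta @ C.T + np.outer(eta[:, i], C[:, i])
            lower = np.full(B, -np.inf)
            upper = np.full(B, np.inf)
            for r in range(C.shape[0]):
                c = C[r, i]
                if c > 1e-14:
                    lower = np.maximum(lower, resid[:, r] / c)
                elif c < -1e-14:
                    upper = np.minimum(upper, resid[:, r] / c)
            a_std = (lower - mu) / cond_sd[i]
            b_std = (upper - mu) / cond_sd[i]
            eta[:, i] = mu + cond_sd[i] * _sample_interval_std_normal(
                a_std, b_std, rng
            )
    return alpha_hat + eta


def percentile_ci(samples: np.ndarray, level: float = 0.95) -> np.ndarray:
    """Elementwise empirical percentile intervals, (coef x 2)."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    lo = (1.0 - level) / 2.0
    return np.quantile(samples, [lo, 1.0 - lo], axis=0).T


def normal_inference(
    fit: CGAIMFit, B: int = 500, level: float = 0.95, seed: int = 0
) -> InferenceResult:
    """Truncated-normal confidence intervals for the stacked weights."""
    Sigma, s2 = alpha_covariance(fit.V, fit.rss, fit.n, fit.edf)
    C, b = block_constraints(fit.spec.groups)
    try:
        C_full, b_full = augment_constraints(C, b)
    except ValueError:
        # over-constrained system (more rows than weights): the square-C
        # transform is undefined, so sample the truncated normal on the
        # polyhedron directly
        samples = _gibbs_polyhedral(
            fit.alpha_vector, Sigma, C, b, B, np.random.default_rng(seed)
        )
    else:
        samples = truncated_normal_samples(
            fit.alpha_vector, Sigma, C_full, b_full, B, seed
        )
    return InferenceResult(
        method="normal",
        samples=samples,
        ci=percentile_ci(samples, level),
        level=level,
        B=B,
        sigma2_hat=s2,
        Sigma_alpha=Sigma,
    )


def residual_bootstrap(
    fit: CGAIMFit,
    data,
    response: str = "y",
    B: int = 500,
    level: float = 0.95,
    seed: int = 0,
    warm_start: bool = True,
    max_iter: int = 25,
    curve_grid_size: int = 0,
) -> InferenceResult:
    """Residual-bootstrap distribution of the weights (and optionally curves).

    Residuals are resampled with replacement onto the fitted values and
    the model refit on each pseudo-response, warm-started at the
    estimated weights.  Failed refits are dropped and counted.
    """
    rng = np.random.default_rng(seed)
    n = fit.n
    eps = fit.residuals
    yhat = fit.fitted
    base = {c: np.asarray(data[c], dtype=float) for c in _used_columns(fit.spec)}
    alpha0 = fit.alpha_vector if warm_start else None
    rows, beta_rows, failed = [], [], 0
    curves: list[list[np.ndarray]] | None = None
    grid = None
    if curve_grid_size:
        grid = np.linspace(
            fit.index_values.min(axis=0),
            fit.index_values.max(axis=0),
            curve_grid_size,
        ).T  # p x grid
        curves = [[] for _ in fit.spec.groups]
    for _ in range(B):
        yb = yhat + eps[rng.integers(0, n, size=n)]
        sample = dict(base)
        sample[response] = yb
        try:
            fb = fit_cgaim(
                fit.spec, sample, response, alpha0=alpha0, max_iter=max_iter
            )
        except Exception as exc:  # noqa: BLE001 - replicate dropped
            failed += 1
            logger.debug("bootstrap refit failed: %s", exc)
            continue
        rows.append(fb.alpha_vector)
        beta_rows.append(fb.beta)
        if curves is not None:
            for j, g in enumerate(grid):
                curves[j].append(
                    fb.additive.beta[j] * fb.additive.ridge_terms[j].evaluate(g)
                    if j < len(fb.additive.ridge_terms)
                    else np.zeros_like(g)
                )
    if failed > 0.1 * B:
        logger.warning("%d of %d bootstrap refits failed", failed, B)
    samples = np.asarray(rows)
    return InferenceResult(
        method="bootstrap",
        samples=samples,
        ci=percentile_ci(samples, level),
        level=level,
        B=B,
        n_failed=failed,
        beta_samples=np.asarray(beta_rows),
        curve_grid=grid,
        curve_samples=[np.asarray(c) for c in curves] if curves else None,
    )


def _used_columns(spec) -> list[str]:
    cols = [c for g in spec.groups for c in g.columns]
    cols += [c.name for c in spec.covariates]
    return cols
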