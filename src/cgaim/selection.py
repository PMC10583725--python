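"""Effective degrees of freedom, GCV, and forward stepwise index selection.

Model complexity cannot be read off a hat matrix here (the weights enter
nonlinearly), so the edf charges one degree of freedom per index and per
covariate block, plus a smoothing edf per ridge function (the calibrated
unconstrained trace minus ``c = 1.5`` per active shape constraint) and a
weight edf per index (the number of weights minus the number of active
linear constraints).  The GCV criterion built from this edf drives a
forward stepwise search over candidate indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SelectionPath",
    "edf_alpha",
    "edf_g_term",
    "edf_total",
    "gcv",
    "forward_select",
]

logger = logging.getLogger(__name__)


def edf_alpha(group, fit) -> float:
    """Weight-vector edf: group size minus independent active constraints.

    The discount is the rank of the active rows of C_j at the estimate
    (the codimension of the face the solution sits on); redundant active
    rows do not reduce the effective dimension further.  Floored at 0.
    """
    act = fit.group_active(group)
    n_active = (
        int(np.linalg.matrix_rank(group.C[act])) if len(act) else 0
    )
    return float(max(group.size - n_active, 0))


def edf_g_term(term, c: float = 1.5) -> float:
    """Smoothing edf of one ridge term, discounted for active shape rows.

    Active rows are counted as the rank of the active shape-constraint
    set, each charged ``c`` (about 1.5 to account for the smoothing
    penalization); floored at 1.
    """
    val = term.edf_unconstrained - c * term.active_shape_rank
    return float(max(val, 1.0))


def edf_total(fit, c: float = 1.5) -> float:
    """Total model edf: p + d + sum(edf_g) + sum(edf_alpha).

    ``d`` counts covariate blocks: one per smooth covariate plus one for
    the linear block if present.  Each smooth term contributes its
    face-restricted hat-matrix trace (the Stein df of the constrained
    penalized smoother); ``edf_g_term`` provides the classical
    count-based approximation for reference.
    """
    spec = fit.spec
    active_groups = [g for g in spec.groups if g.name not in fit.null_groups]
    p = len(active_groups)
    n_smooth = len(fit.additive.covariate_terms)
    d = n_smooth + (1 if fit.additive.theta.size else 0)
    e_g = sum(
        t.edf_face
        for t in fit.additive.ridge_terms + fit.additive.covariate_terms
    )
    e_a = sum(edf_alpha(g, fit) for g in active_groups)
    total = p + d + e_g + e_a
    if total >= fit.n:
        raise ValueError("model edf exceeds the sample size")
    return float(total)


def gcv(rss: float, n: int, edf: float) -> float:
    """Generalized cross-validation score (rss/n) / (1 - edf/n)^2."""
    if edf >= n:
        raise ValueError("GCV undefined for edf >= n")
    return (rss / n) / (1.0 - edf / n) ** 2


@dataclass
class SelectionPath:
    """Record of a forward stepwise search."""

    steps: list[dict]
    best: list[str]
    best_gcv: float
    base_gcv: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.steps)


def _base_gcv(spec, data, response: str) -> float:
    """GCV of the intercept(+covariates) model with no index."""
    y = np.asarray(data[response], dtype=float)
    n = y.shape[0]
    if not spec.covariates:
        rss = float(np.sum((y - y.mean()) ** 2))
        return gcv(rss, n, 0.0)
    from .smoothing import fit_constrained_additive

    smooth, linear = [], []
    for cov in spec.covariates:
        w = np.asarray(data[cov.name], dtype=float)
        (smooth.append((w, cov.f_shape)) if cov.mode == "smooth" else linear.append(w))
    fit = fit_constrained_additive(
        y,
        [],
        [],
        smooth_covs=smooth,
        linear_covs=np.column_stack(linear) if linear else None,
        target_df=spec.target_df,
        n_basis=spec.n_basis,
        select_df=spec.smooth_select == "gcv",
    )
    n_smooth = len(fit.covariate_terms)
    d = n_smooth + (1 if fit.theta.size else 0)
    e_g = sum(t.edf_face for t in fit.covariate_terms)
    return gcv(fit.rss, n, d + e_g)


def forward_select(
    spec,
    data,
    response: str = "y",
    candidates: list[str] | None = None,
) -> SelectionPath:
    """Forward stepwise search adding, at each step, the GCV-minimizing index.

    Starts from the intercept (plus any covariates in the spec) and
    stops when no candidate addition strictly lowers the GCV.  Ties are
    broken by candidate order.
    """
    from .estimator import fit_cgaim

    names = [g.name for g in spec.groups]
    candidates = list(candidates) if candidates is not None else names
    if not candidates:
        raise ValueError("candidates must be nonempty")
    current: list[str] = []
    best_gcv = _base_gcv(spec, data, response)
    base = best_gcv
    steps: list[dict] = []
    remaining = list(candidates)
    while remaining:
        trial_scores: list[tuple[float, str, float]] = []
        for name in remaining:
            try:
                f = fit_cgaim(spec.subset(current + [name]), data, response)
            except Exception as exc:  # noqa: BLE001 - candidate skipped
                logger.warning("candidate %s failed: %s", name, exc)
                continue
            trial_scores.append((f.gcv, name, f.edf))
        if not trial_scores:
            break
        g_best, n_best, e_best = min(
            trial_scores, key=lambda t: (t[0], candidates.index(t[1]))
        )
        if g_best >= best_gcv:
            break
        current.append(n_best)
        remaining.remove(n_best)
        best_gcv = g_best
        steps.append({"added_term": n_best, "gcv": g_best, "edf": e_best})
    return SelectionPath(steps=steps, best=current, best_gcv=best_gcv, base_gcv=base)
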