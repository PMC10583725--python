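"""Model specification and linear constraint systems on index weights.

A CGAIM relates a response to a small number of *indices*, each a linear
combination ``z_j = alpha_j' x_j`` of a predeclared, disjoint group of
predictors.  Interpretability comes from linear inequality constraints
``C_j alpha_j >= b_j`` on each weight vector (positivity, monotone
orderings with lag, weighted averages, ...) and from shape constraints on
the ridge function linking each index to the response.  This module holds
the declarative side: groups, constraint builders, feasibility checks and
the square augmentation needed by the truncated-normal inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.optimize import linprog

__all__ = [
    "SHAPES",
    "ShapeConstraint",
    "IndexGroup",
    "CovariateSpec",
    "CGAIMSpec",
    "monotone_constraint",
    "sign_constraint",
    "block_constraints",
    "feasibility",
    "augment_constraints",
]

#: Recognized ridge/covariate shape constraints.  Combination kinds imply
#: both component constraints simultaneously.
SHAPES = frozenset(
    {
        "none",
        "increasing",
        "decreasing",
        "convex",
        "concave",
        "convex_increasing",
        "convex_decreasing",
        "concave_increasing",
        "concave_decreasing",
    }
)

#: Sentinel standing in for -inf bounds on augmented constraint rows.
#: Large enough to never be active on any realistic weight scale.
NEG_INF_BOUND = -1e10


@dataclass(frozen=True)
class ShapeConstraint:
    kind: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in SHAPES:
            raise ValueError(f"unknown shape constraint {self.kind!r}")

    @property
    def monotone(self) -> str | None:
        for d in ("increasing", "decreasing"):
            if self.kind == d or self.kind.endswith("_" + d):
                return d
        return None

    @property
    def curvature(self) -> str | None:
        for c in ("convex", "concave"):
            if self.kind == c or self.kind.startswith(c + "_"):
                return c
        return None


def monotone_constraint(l: int, direction: str) -> np.ndarray:
    """(l-1) x l matrix whose rows encode a monotone ordering of weights.

    For ``decreasing``, row p reads ``alpha_p - alpha_{p+1} >= 0``:
    entry (p, q) is 1 when p = q, -1 when p = q - 1, 0 otherwise.
    ``increasing`` is the row-wise negation.
    """
    if l < 2:
        raise ValueError("monotone ordering needs at least 2 weights")
    if direction not in {"increasing", "decreasing"}:
        raise ValueError(f"unknown direction {direction!r}")
    C = np.zeros((l - 1, l))
    idx = np.arange(l - 1)
    C[idx, idx] = 1.0
    C[idx, idx + 1] = -1.0
    return -C if direction == "increasing" else C


def sign_constraint(l: int, sign: str = "nonnegative") -> np.ndarray:
    """Identity constraint matrix forcing every weight to be nonnegative."""
    if l < 1:
        raise ValueError("need at least one weight")
    if sign != "nonnegative":
        raise ValueError(f"unknown sign constraint {sign!r}")
    return np.eye(l)


_TEMPLATES = {
    "nonnegative": lambda l: sign_constraint(l),
    "increasing": lambda l: monotone_constraint(l, "increasing"),
    "decreasing": lambda l: monotone_constraint(l, "decreasing"),
}


def _dedup_rows(C: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    seen: list[int] = []
    for i in range(C.shape[0]):
        dup = any(
            np.allclose(C[i], C[j]) and np.isclose(b[i], b[j]) for j in seen
        )
        if not dup:
            seen.append(i)
    return C[seen], b[seen]


@dataclass
class IndexGroup:
    """A named group of predictors forming one index.

    ``constraints`` may mix template names ({nonnegative, increasing,
    decreasing}) and explicit (rows x l) matrices; rows are stacked into
    C.  ``b`` defaults to zero.  ``g_shape`` constrains the ridge
    function; ``identifiability`` fixes the scale of alpha.
    """

    name: str
    columns: list[str]
    constraints: list = field(default_factory=list)
    b: np.ndarray | None = None
    g_shape: ShapeConstraint = field(default_factory=ShapeConstraint)
    identifiability: str = "unit_norm_first_positive"

    def __post_init__(self) -> None:
        if isinstance(self.g_shape, str):
            self.g_shape = ShapeConstraint(self.g_shape)
        if len(self.columns) < 2:
            raise ValueError(f"group {self.name!r} needs >= 2 columns")
        if self.identifiability not in {"unit_norm_first_positive", "sum_to_one"}:
            raise ValueError(
                f"unknown identifiability {self.identifiability!r}"
            )
        l = self.size
        blocks = []
        for c in self.constraints:
            if isinstance(c, str):
                if c not in _TEMPLATES:
                    raise ValueError(f"unknown constraint template {c!r}")
                blocks.append(_TEMPLATES[c](l))
            else:
                M = np.atleast_2d(np.asarray(c, dtype=float))
                if M.shape[1] != l:
                    raise ValueError(
                        f"constraint matrix for group {self.name!r} has "
                        f"{M.shape[1]} columns, expected {l}"
                    )
                blocks.append(M)
        C = np.vstack(blocks) if blocks else np.zeros((0, l))
        b = (
            np.zeros(C.shape[0])
            if self.b is None
            else np.asarray(self.b, dtype=float)
        )
        if b.shape[0] != C.shape[0]:
            raise ValueError("b length does not match number of constraint rows")
        if self.identifiability == "sum_to_one":
            ones = np.ones((1, l))
            e1 = np.zeros((1, l))
            e1[0, 0] = 1.0
            C = np.vstack([C, ones, -ones, e1])
            b = np.concatenate([b, [1.0, -1.0, 0.0]])
        self.C, self.b = _dedup_rows(C, b)
        if self.C.shape[0] and np.linalg.matrix_rank(self.C) < min(self.C.shape):
            # full row rank (after dedup) is required by augmentation;
            # redundant-but-consistent rows are tolerated at fit time
            pass
        lp = linprog(
            np.zeros(l),
            A_ub=-self.C if self.C.shape[0] else None,
            b_ub=-self.b if self.C.shape[0] else None,
            bounds=[(-100.0, 100.0)] * l,
            method="highs",
        )
        if not lp.success:
            raise ValueError(
                f"constraint system of group {self.name!r} is infeasible"
            )

    @property
    def size(self) -> int:
        return len(self.columns)

    @property
    def homogeneous(self) -> bool:
        return bool(np.all(self.b == 0.0))

    def normalize(self, alpha: np.ndarray, *, allow_flip: bool = True) -> np.ndarray:
        """Rescale alpha to the group's identifiability normalization."""
        alpha = np.asarray(alpha, dtype=float)
        if self.identifiability == "sum_to_one":
            s = alpha.sum()
            if not self.homogeneous or abs(s) < 1e-12:
                return alpha  # constraints themselves carry the scale
            return alpha / s
        nrm = np.linalg.norm(alpha)
        if nrm < 1e-12:
            return alpha
        out = alpha / nrm
        if allow_flip and out[0] < 0 and self.homogeneous:
            flipped = -out
            if np.all(self.C @ flipped >= self.b - 1e-10):
                out = flipped
        return out


@dataclass
class CovariateSpec:
    """A covariate outside every index: smooth (with optional shape) or linear."""

    name: str
    mode: str = "smooth"
    f_shape: ShapeConstraint = field(default_factory=ShapeConstraint)

    def __post_init__(self) -> None:
        if isinstance(self.f_shape, str):
            self.f_shape = ShapeConstraint(self.f_shape)
        if self.mode not in {"smooth", "linear"}:
            raise ValueError(f"unknown covariate mode {self.mode!r}")
        if self.mode == "linear" and self.f_shape.kind != "none":
            raise ValueError("linear covariates carry no shape constraint")


@dataclass
class CGAIMSpec:
    """Full model description handed to the estimator."""

    groups: list[IndexGroup]
    covariates: list[CovariateSpec] = field(default_factory=list)
    target_df: float = 10.0
    n_basis: int = 15
    tol: float = 1e-6
    max_iter: int = 50
    init_mode: str = "regression"
    smooth_select: str = "fixed"
    seed: int = 0
    active_tol: float = 1e-8

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one index group is required")
        if self.target_df < 2:
            raise ValueError("target_df must be >= 2")
        if self.n_basis <= self.target_df:
            raise ValueError("n_basis must exceed target_df")
        if self.smooth_select not in {"fixed", "gcv"}:
            raise ValueError("smooth_select must be 'fixed' or 'gcv'")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        all_cols = [c for g in self.groups for c in g.columns]
        if len(set(all_cols)) != len(all_cols):
            raise ValueError("a predictor may not enter two indices")

    def subset(self, names: list[str]) -> "CGAIMSpec":
        """Spec restricted to the named groups (covariates kept)."""
        keep = [g for g in self.groups if g.name in names]
        return CGAIMSpec(
            groups=keep,
            covariates=list(self.covariates),
            target_df=self.target_df,
            n_basis=self.n_basis,
            tol=self.tol,
            max_iter=self.max_iter,
            init_mode=self.init_mode,
            smooth_select=self.smooth_select,
            seed=self.seed,
            active_tol=self.active_tol,
        )


def block_constraints(groups: list[IndexGroup]) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-group systems into the global block-diagonal C, b."""
    if not groups:
        raise ValueError("groups must be nonempty")
    sizes = [g.size for g in groups]
    rows = [g.C.shape[0] for g in groups]
    C = np.zeros((sum(rows), sum(sizes)))
    b = np.concatenate([g.b for g in groups]) if sum(rows) else np.zeros(0)
    r = c = 0
    for g in groups:
        C[r : r + g.C.shape[0], c : c + g.size] = g.C
        r += g.C.shape[0]
        c += g.size
    return C, b


def feasibility(
    C: np.ndarray,
    b: np.ndarray,
    alpha: np.ndarray,
    tol: float = 1e-8,
) -> tuple[bool, np.ndarray]:
    """Check C alpha >= b - tol; return (feasible, indices of active rows)."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    b = np.asarray(b, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if C.shape[1] != alpha.shape[0] or C.shape[0] != b.shape[0]:
        raise ValueError("dimension mismatch in feasibility check")
    slack = C @ alpha - b
    return bool(slack.min(initial=0.0) >= -tol), np.flatnonzero(
        np.abs(slack) <= tol
    )


def augment_constraints(
    C: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Augment C to a square invertible matrix for inference.

    Rows spanning the orthogonal complement of C's row space are appended
    with -inf (sentinel) bounds, so the added rows are never active and
    any alpha with ``C alpha >= b`` also satisfies the augmented system.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    b = np.asarray(b, dtype=float)
    m, l = C.shape
    if m > l:
        raise ValueError(
            "more constraint rows than weights: square augmentation is "
            "undefined; use the bootstrap for inference"
        )
    if m and np.linalg.matrix_rank(C) < m:
        raise ValueError(
            "constraint matrix is row rank deficient; remove redundant rows"
        )
    if m == l:
        return C.copy(), b.copy()
    C0 = linalg.null_space(C).T if m else np.eye(l)
    C_full = np.vstack([C, C0])
    b_full = np.concatenate([b, np.full(l - m, NEG_INF_BOUND)])
    return C_full, b_full
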