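"""Synthetic data generators and scoring for the simulation studies.

Two designs are provided.  The *three-index* mechanism mimics an
environmental-epidemiology setting: three groups of four multivariate-
normal predictors (exchangeable within-group correlation ``rho``), one
index with sharply decreasing weights and a log-shaped ridge (air
pollution / mortality), one with moving-average weights and a sigmoid
ridge (soft threshold), and one with delayed-peak weights and a U-shaped
ridge (temperature / mortality).  The *exposome* design draws 28
predictors in five blocks and a linear response whose R-squared is
calibrated to ``3 p* / 100`` for ``p*`` non-null +/-1 weights.

The ridge functions are centered and scaled to unit norm under a
standard-normal index (Gauss-Hermite quadrature), so each active term
contributes unit signal variance at ``rho = 0`` and the noise levels
``sigma = 0.2, 0.5, 1`` span high to moderate signal-to-noise ratios.
Every generator is seed-deterministic and returns the truth needed for
scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .constraints import CGAIMSpec, IndexGroup
from .estimator import fit_cgaim
from .inference import normal_inference, residual_bootstrap
from .selection import forward_select

__all__ = [
    "SimulationScenario",
    "ExposomeScenario",
    "gen_three_index",
    "three_index_spec",
    "gen_exposome",
    "rmse_alpha",
    "selection_metrics",
    "bias_corrected_coverage",
    "run_selection_experiment",
    "run_coverage_experiment",
]

GROUP_NAMES = ("index1", "index2", "index3")

_TRUE_ALPHA_RAW = {
    "index1": np.array([0.4, 0.3, 0.2, 0.1]),  # sharply decreasing
    "index2": np.array([0.25, 0.25, 0.25, 0.25]),  # moving average
    "index3": np.array([0.1, 0.4, 0.35, 0.15]),  # delayed peak
}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)

TRUE_ALPHA = {k: _unit(v) for k, v in _TRUE_ALPHA_RAW.items()}


def _g_log(t):
    # log(t + 5) with a matching linear extension below t0 so the truth
    # is increasing and concave on the whole real line
    t = np.asarray(t, dtype=float)
    t0 = -4.9
    return np.where(
        t > t0,
        np.log(np.clip(t, t0, None) + 5.0),
        np.log(t0 + 5.0) + (t - t0) / (t0 + 5.0),
    )


def _g_sigmoid(t):
    return 1.0 / (1.0 + np.exp(-4.0 * np.asarray(t)))


def _g_ushape(t):
    return (np.asarray(t) - 0.5) ** 2


@lru_cache(maxsize=None)
def _std_constants(name: str) -> tuple[float, float]:
    """Mean and RMS of a ridge function under a standard normal argument."""
    fn = {"log": _g_log, "sigmoid": _g_sigmoid, "ushape": _g_ushape}[name]
    x, w = np.polynomial.hermite.hermgauss(120)
    z = np.sqrt(2.0) * x
    w = w / np.sqrt(np.pi)
    mu = float(np.sum(w * fn(z)))
    sd = float(np.sqrt(np.sum(w * (fn(z) - mu) ** 2)))
    return mu, sd


def true_ridge(name: str):
    """Centered, unit-norm version of a named true ridge function."""
    fn = {"log": _g_log, "sigmoid": _g_sigmoid, "ushape": _g_ushape}[name]
    mu, sd = _std_constants(name)

    def g(t):
        return (fn(t) - mu) / sd

    return g


RIDGE_KINDS = {"index1": "log", "index2": "sigmoid", "index3": "ushape"}


@dataclass
class SimulationScenario:
    """Three-index generator parameters."""

    n: int = 1000
    rho: float = 0.0
    sigma: float = 0.5
    seed: int = 0
    beta: np.ndarray = field(default_factory=lambda: np.ones(3))
    beta0: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.sigma < 0.0:
            raise ValueError("sigma must be nonnegative")


def _mvn_exchangeable(
    rng: np.random.Generator, n: int, l: int, rho: float
) -> np.ndarray:
    """MVN draws with unit variance and exchangeable correlation rho."""
    if rho == 0.0:
        return rng.standard_normal((n, l))
    shared = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, l))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own


def gen_three_index(scenario: SimulationScenario) -> dict:
    """Generate one data set from the three-index mechanism.

    Returns ``{"data": DataFrame, "truth": {...}}``; the data frame has
    columns ``x{j}_{k}`` for group j and the response ``y``.
    """
    rng = np.random.default_rng(scenario.seed)
    data: dict[str, np.ndarray] = {}
    signal = np.full(scenario.n, scenario.beta0)
    for j, name in enumerate(GROUP_NAMES):
        X = _mvn_exchangeable(rng, scenario.n, 4, scenario.rho)
        for k in range(4):
            data[f"x{j + 1}_{k + 1}"] = X[:, k]
        if scenario.beta[j] != 0.0:
            z = X @ TRUE_ALPHA[name]
            signal = signal + scenario.beta[j] * true_ridge(RIDGE_KINDS[name])(z)
    y = signal + scenario.sigma * rng.standard_normal(scenario.n)
    data["y"] = y
    return {
        "data": pd.DataFrame(data),
        "truth": {
            "alpha": dict(TRUE_ALPHA),
            "beta": np.asarray(scenario.beta, dtype=float),
            "beta0": scenario.beta0,
            "signal": signal,
            "ridges": dict(RIDGE_KINDS),
        },
    }


def three_index_spec(
    model: str = "cgaim",
    groups: list[str] | None = None,
    target_df: float = 10.0,
    seed: int = 0,
) -> CGAIMSpec:
    """Model specification matching the three-index generator.

    ``cgaim``: positivity on all weights, decreasing ordering on the
    first two indices (matching the generated orderings), increasing
    shapes on the first two ridges and convex on the third.  ``gaim``:
    identifiability constraints only, no shapes.  ``mgaim``: the
    orderings of indices 1 and 2 reversed (mis-specified on purpose).
    The constrained models use the fixed 10-df smoothness; the
    unconstrained ``gaim`` selects each term's smoothness by GCV.
    """
    if model not in {"cgaim", "gaim", "mgaim"}:
        raise ValueError(f"unknown model {model!r}")
    wanted = groups if groups is not None else list(GROUP_NAMES)
    cons = {
        "cgaim": {
            "index1": ["nonnegative", "decreasing"],
            "index2": ["nonnegative", "decreasing"],
            "index3": ["nonnegative"],
        },
        "mgaim": {
            "index1": ["nonnegative", "increasing"],
            "index2": ["nonnegative", "increasing"],
            "index3": ["nonnegative"],
        },
        "gaim": {"index1": [], "index2": [], "index3": []},
    }[model]
    shapes = (
        {"index1": "increasing", "index2": "increasing", "index3": "convex"}
        if model != "gaim"
        else {"index1": "none", "index2": "none", "index3": "none"}
    )
    built = []
    for name in wanted:
        j = GROUP_NAMES.index(name) + 1
        built.append(
            IndexGroup(
                name=name,
                columns=[f"x{j}_{k}" for k in range(1, 5)],
                constraints=cons[name],
                g_shape=shapes[name],
            )
        )
    return CGAIMSpec(
        groups=built,
        target_df=target_df,
        smooth_select="gcv" if model == "gaim" else "fixed",
        seed=seed,
    )


@dataclass
class ExposomeScenario:
    """Exposome-style linear design with block-correlated predictors."""

    n: int = 1200
    p_star: int = 5
    seed: int = 0
    group_sizes: tuple = (4, 5, 4, 5, 10)
    within_rho: float = 0.3
    correlation: np.ndarray | None = None

    @property
    def d(self) -> int:
        return int(sum(self.group_sizes))


def gen_exposome(scenario: ExposomeScenario) -> dict:
    """Generate an exposome-style data set with calibrated R-squared.

    ``p_star`` predictors get weights of +/-1 (equal probability); the
    noise variance is solved from the realized signal variance so that
    the model R-squared equals ``3 p* / 100``.
    """
    d = scenario.d
    if scenario.p_star > d:
        raise ValueError("p_star cannot exceed the number of predictors")
    rng = np.random.default_rng(scenario.seed)
    if scenario.correlation is not None:
        R = np.asarray(scenario.correlation, dtype=float)
        eig = np.linalg.eigvalsh(R)
        if eig.min() < -1e-10:
            raise ValueError("user correlation matrix is not positive semidefinite")
        L = np.linalg.cholesky(R + 1e-10 * np.eye(d))
        X = rng.standard_normal((scenario.n, d)) @ L.T
    else:
        blocks = [
            _mvn_exchangeable(rng, scenario.n, l, scenario.within_rho)
            for l in scenario.group_sizes
        ]
        X = np.hstack(blocks)
    alpha = np.zeros(d)
    if scenario.p_star:
        idx = rng.choice(d, size=scenario.p_star, replace=False)
        alpha[idx] = rng.choice([-1.0, 1.0], size=scenario.p_star)
    signal = X @ alpha
    r2 = 3.0 * scenario.p_star / 100.0
    if scenario.p_star:
        var_sig = float(np.var(signal))
        var_eps = var_sig * (1.0 - r2) / r2
    else:
        var_eps = 1.0
    y = signal + np.sqrt(var_eps) * rng.standard_normal(scenario.n)
    cols = {f"e{k + 1}": X[:, k] for k in range(d)}
    cols["y"] = y
    return {
        "data": pd.DataFrame(cols),
        "truth": {"alpha": alpha, "r2": r2, "signal": signal},
    }


def rmse_alpha(
    estimates: list[np.ndarray] | np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-coefficient RMSE over replicates and its mean over coefficients."""
    E = np.atleast_2d(np.asarray(estimates, dtype=float))
    truth = np.asarray(truth, dtype=float)
    per = np.sqrt(np.mean((E - truth) ** 2, axis=0))
    return per, float(per.mean())


def selection_metrics(
    selected, true_set, universe
) -> dict[str, float | None]:
    """Sensitivity and specificity of a selected index set.

    Sensitivity: share of true indices that were selected.  Specificity:
    share of non-true indices that were discarded.  Empty denominators
    yield None (excluded from averages).
    """
    selected, true_set, universe = set(selected), set(true_set), set(universe)
    negatives = universe - true_set
    sens = (
        len(selected & true_set) / len(true_set) if true_set else None
    )
    spec = (
        len(negatives - selected) / len(negatives) if negatives else None
    )
    return {"sensitivity": sens, "specificity": spec}


def bias_corrected_coverage(
    ci_sets: np.ndarray, alpha_bar: np.ndarray
) -> tuple[np.ndarray, float]:
    """Share of replicate intervals containing the mean estimate.

    ``ci_sets`` is (replicates x coefficients x 2).  Returns the
    per-coefficient proportions and their macro average.
    """
    ci = np.asarray(ci_sets, dtype=float)
    if ci.ndim != 3 or ci.shape[0] < 2:
        raise ValueError("need >= 2 replicates of (coef x 2) intervals")
    inside = (ci[:, :, 0] <= alpha_bar) & (alpha_bar <= ci[:, :, 1])
    per = inside.mean(axis=0)
    return per, float(per.mean())


def run_selection_experiment(
    n_reps: int = 100,
    sigma: float = 0.5,
    seed: int = 0,
    n: int = 1000,
    rho: float = 0.0,
) -> pd.DataFrame:
    """Forward-GCV selection study: sensitivity/specificity, CGAIM vs GAIM.

    Each replicate draws 1 or 2 true indices at random, generates data
    with unit coefficients on those indices only, and runs the forward
    stepwise search for both the constrained and unconstrained models.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_reps):
        p_star = int(rng.integers(1, 3))
        true_idx = sorted(rng.choice(3, size=p_star, replace=False))
        beta = np.zeros(3)
        beta[true_idx] = 1.0
        scen = SimulationScenario(
            n=n,
            rho=rho,
            sigma=sigma,
            seed=int(rng.integers(2**31 - 1)),
            beta=beta,
        )
        sim = gen_three_index(scen)
        true_names = {GROUP_NAMES[i] for i in true_idx}
        for model in ("cgaim", "gaim"):
            spec = three_index_spec(model)
            path = forward_select(spec, sim["data"])
            m = selection_metrics(path.best, true_names, GROUP_NAMES)
            rows.append(
                {
                    "replicate": r,
                    "model": model,
                    "p_star": p_star,
                    "selected": ",".join(path.best),
                    "true": ",".join(sorted(true_names)),
                    **m,
                }
            )
    return pd.DataFrame(rows)


def run_coverage_experiment(
    n_reps: int = 100,
    B: int = 200,
    sigma: float = 0.5,
    method: str = "bootstrap",
    seed: int = 0,
    n: int = 1000,
    rho: float = 0.0,
    level: float = 0.95,
) -> dict:
    """Bias-corrected coverage study of the weight confidence intervals."""
    if method not in {"bootstrap", "normal"}:
        raise ValueError("method must be 'bootstrap' or 'normal'")
    rng = np.random.default_rng(seed)
    spec = three_index_spec("cgaim")
    cis, alphas = [], []
    for _ in range(n_reps):
        scen = SimulationScenario(
            n=n, rho=rho, sigma=sigma, seed=int(rng.integers(2**31 - 1))
        )
        sim = gen_three_index(scen)
        fit = fit_cgaim(spec, sim["data"])
        inf_seed = int(rng.integers(2**31 - 1))
        if method == "bootstrap":
            res = residual_bootstrap(fit, sim["data"], B=B, level=level, seed=inf_seed)
        else:
            res = normal_inference(fit, B=B, level=level, seed=inf_seed)
        cis.append(res.ci)
        alphas.append(fit.alpha_vector)
    cis = np.asarray(cis)
    alphas = np.asarray(alphas)
    alpha_bar = alphas.mean(axis=0)
    per, macro = bias_corrected_coverage(cis, alpha_bar)
    return {
        "per_coefficient": per,
        "macro": macro,
        "alpha_bar": alpha_bar,
        "alpha_estimates": alphas,
        "ci_sets": cis,
        "method": method,
    }
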