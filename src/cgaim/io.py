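"""Data reading, lag-matrix construction and model configuration files.

A run is described by a YAML (or JSON) configuration declaring the
response column, predictor groups with their constraints and ridge
shapes, optional covariates, optional lag expansions (turning a single
series into a ``var_lag0..var_lagK`` group, the usual setup for
distributed-lag exposure indices), and fitting controls.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constraints import CGAIMSpec, CovariateSpec, IndexGroup

__all__ = ["LagSpec", "RunConfig", "read_table", "build_lag_matrix", "apply_lags", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class LagSpec:
    """Expand a series into lagged copies (lag 0 = same day)."""

    variable: str
    lags: list[int]

    def __post_init__(self) -> None:
        self.lags = sorted(set(int(l) for l in self.lags))
        if any(l < 0 for l in self.lags):
            raise ValueError("lags must be nonnegative")

    @property
    def columns(self) -> list[str]:
        return [f"{self.variable}_lag{l}" for l in self.lags]


def read_table(path, used_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV with a header row; coerce used columns to numeric.

    Rows with missing values in any used column are dropped (logged);
    missing values in unused columns are ignored.
    """
    df = pd.read_csv(path)
    cols = list(df.columns) if used_columns is None else list(used_columns)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"columns not found in {path}: {missing}")
    for c in cols:
        df[c] = pd.to_numeric(df[c], errors="raise")
    before = len(df)
    df = df.dropna(subset=cols).reset_index(drop=True)
    if len(df) < before:
        logger.info("dropped %d rows with missing values", before - len(df))
    return df


def build_lag_matrix(table: pd.DataFrame, lagspec: LagSpec) -> pd.DataFrame:
    """Lagged copies of one series; the first max-lag rows are dropped."""
    series = np.asarray(table[lagspec.variable], dtype=float)
    n = series.shape[0]
    max_lag = max(lagspec.lags)
    if max_lag >= n:
        raise ValueError("maximum lag must be below the number of rows")
    out = {
        f"{lagspec.variable}_lag{l}": series[max_lag - l : n - l]
        for l in lagspec.lags
    }
    return pd.DataFrame(out)


def apply_lags(table: pd.DataFrame, lagspecs: list[LagSpec]) -> pd.DataFrame:
    """Add all lag columns and trim the first global max-lag rows."""
    if not lagspecs:
        return table
    max_lag = max(max(ls.lags) for ls in lagspecs)
    out = table.iloc[max_lag:].reset_index(drop=True)
    for ls in lagspecs:
        series = np.asarray(table[ls.variable], dtype=float)
        for l in ls.lags:
            out[f"{ls.variable}_lag{l}"] = series[
                max_lag - l : len(series) - l
            ]
    return out


@dataclass
class RunConfig:
    """Parsed run configuration."""

    response: str
    spec: CGAIMSpec
    lags: list[LagSpec] = field(default_factory=list)

    @property
    def used_columns(self) -> list[str]:
        lag_cols = {c for ls in self.lags for c in ls.columns}
        cols = [self.response]
        cols += [ls.variable for ls in self.lags]
        for g in self.spec.groups:
            cols += [c for c in g.columns if c not in lag_cols]
        cols += [c.name for c in self.spec.covariates]
        return list(dict.fromkeys(cols))


def load_config(path) -> RunConfig:
    """Load a YAML/JSON model configuration into a RunConfig."""
    text = Path(path).read_text()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    groups = []
    for g in cfg["groups"]:
        groups.append(
            IndexGroup(
                name=g["name"],
                columns=list(g["columns"]),
                constraints=g.get("constraints", []),
                b=np.asarray(g["b"], dtype=float) if "b" in g else None,
                g_shape=g.get("shape", "none"),
                identifiability=g.get(
                    "identifiability", "unit_norm_first_positive"
                ),
            )
        )
    covs = [
        CovariateSpec(
            name=c["name"],
            mode=c.get("mode", "smooth"),
            f_shape=c.get("shape", "none"),
        )
        for c in cfg.get("covariates", [])
    ]
    fit = cfg.get("fit", {})
    spec = CGAIMSpec(
        groups=groups,
        covariates=covs,
        target_df=float(fit.get("target_df", 10.0)),
        n_basis=int(fit.get("n_basis", 15)),
        tol=float(fit.get("tol", 1e-6)),
        max_iter=int(fit.get("max_iter", 50)),
        init_mode=fit.get("init_mode", "regression"),
        seed=int(fit.get("seed", 0)),
    )
    lags = [
        LagSpec(variable=l["variable"], lags=list(l["lags"]))
        for l in cfg.get("lags", [])
    ]
    return RunConfig(response=cfg["response"], spec=spec, lags=lags)
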