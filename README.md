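# cgaim — constrained groupwise additive index models

`cgaim` builds **interpretable exposure indices** from groups of related
predictors and relates them to a continuous health outcome.  It is aimed
at environmental-epidemiology settings — heat–mortality warning systems,
multipollutant or exposome studies — where analysts want a small number
of weighted summaries of exposures (an index per group of variables)
whose weights respect prior knowledge, rather than a black-box fit.

## The model

Given disjoint predictor groups `X_1, ..., X_p`, optional smooth
covariates `W_k` and linear covariates `U`, the model is

```
Y = β₀ + Σ_j β_j g_j(α_jᵀ X_j) + Σ_k γ_k f_k(W_k) + Uᵀθ + ε
```

where each index `Z_j = α_jᵀ X_j` has weights constrained by a linear
system `C_j α_j ≥ b_j` (positivity, monotone orderings with lag,
weighted averages, ...), and each ridge function `g_j` (and `f_k`) may
carry a shape constraint: monotone, convex/concave, or combinations.
Identifiability comes from unit-norm (or sum-to-one) weights, centered
ridge functions with unit norm, and importances `β_j ≥ 0`.

Estimation alternates two steps until the residual sum of squares
stabilizes:

1. **Ridge update** — at fixed weights, all `g_j`/`f_k` are estimated
   jointly by shape-constrained penalized B-splines: a quadratic program
   on the spline coefficients with difference-cone inequality rows.
   Smoothness is fixed by calibrating each term's penalty to a target of
   10 equivalent degrees of freedom (or selected by per-term GCV for
   unconstrained terms, if requested).
2. **Weight update** — at fixed ridge functions, a constrained
   Gauss–Newton step: the quadratic program
   `min_δ ‖R − Vδ‖²  s.t.  C(α + δ) ≥ b`, where `V` holds the partial
   derivatives `x_ij β_j g_j′(z_ij)` and `R` the current residuals, with
   a step-halving line search that keeps the objective monotone.

Model selection uses a GCV criterion `GCV = (RSS/n)/(1 − edf/n)²` with
`edf = p + d + Σ edf_g + Σ edf_α`, where active constraints reduce the
per-term degrees of freedom, driving a forward stepwise search over
candidate indices.  Inference for the weights is available through a
truncated-multivariate-normal approximation and through a residual
bootstrap.

## Worked example

```python
import numpy as np
from cgaim import fit_cgaim, residual_bootstrap
from cgaim.synthetic import SimulationScenario, gen_three_index, three_index_spec

sim = gen_three_index(SimulationScenario(n=1000, sigma=0.5, seed=11))
spec = three_index_spec("cgaim")   # positivity + monotone orderings + shapes
fit = fit_cgaim(spec, sim["data"])

print({k: np.round(v, 3) for k, v in fit.alpha.items()})
print(f"converged={fit.converged} rss={fit.rss:.1f} edf={fit.edf:.1f} gcv={fit.gcv:.4f}")
```

prints

```
{'index1': array([0.722, 0.557, 0.364, 0.187]),
 'index2': array([0.5, 0.5, 0.5, 0.5]),
 'index3': array([0.185, 0.709, 0.624, 0.271])}
converged=True rss=239.1 edf=37.9 gcv=0.2584
```

The recovered weights sit close to the generator's truth
(`index1 ≈ (0.73, 0.55, 0.37, 0.18)`: sharply decreasing weights, a
log-shaped pollution-like ridge; `index2`: moving-average weights with a
sigmoid ridge; `index3`: a delayed-peak temperature-like U-shape), and
95% bootstrap intervals follow from
`residual_bootstrap(fit, sim["data"], B=500)`.

A command-line interface mirrors the library:

```sh
cgaim simulate --experiment dataset --n 1000 --out sim --seed 7
cgaim fit    --data sim/data.csv --config model.yaml --out fit_out
cgaim select --data sim/data.csv --config model.yaml --out sel_out
cgaim infer  --data sim/data.csv --config model.yaml --out ci_out --method bootstrap
```

with a YAML configuration declaring the response, groups (columns,
constraint templates or explicit matrices, ridge shapes), covariates and
optional distributed-lag expansions (see `docs/methods.md`).

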