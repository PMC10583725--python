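# Methods

This note documents the statistical procedures implemented in `cgaim`,
the choices made where the design was genuinely open, and what the
synthetic test bed does and does not establish.

## Model and identifiability

The constrained groupwise additive index model relates a continuous
response to `p` indices — linear combinations `z_j = α_jᵀ x_j` of
predeclared, disjoint predictor groups — through smooth ridge functions,
plus optional smooth and linear covariates:

```
y_i = β₀ + Σ_j β_j g_j(α_jᵀ x_ij) + Σ_k γ_k f_k(w_ik) + u_iᵀθ + ε_i .
```

Interpretability enters twice: linear inequality constraints
`C_j α_j ≥ b_j` on the weights and shape constraints (monotone,
convex/concave, combinations) on `g_j` and `f_k`.  Identifiability is
fixed by (a) weight normalization — unit norm with positive first
element by default, or sum-to-one, in which case the scale is carried by
the constraint rows themselves — (b) mean-centering of every smooth term
over the sample, with the intercept absorbing the level, and (c)
nonnegative importances `β_j`, obtained as the root-mean-square norm of
the fitted term over the sample (the direction of an effect lives in
`g_j`, not in `β_j`).  RMS rather than an unnormalized L2 norm keeps
`β_j` comparable across sample sizes.

## Shape-constrained smoothing

Each smooth term uses a cubic B-spline basis (default 15 basis
functions) with interior knots at quantiles of the term's current
argument.  The roughness penalty is the squared difference of the
*derivative-spline coefficients* (knot-aware divided differences), which
leaves linear functions exactly unpenalized on arbitrary knots — the
plain second-difference penalty does not, and visibly biases even a
linear truth on quantile knots.

Shapes are imposed as linear inequality rows on the coefficients:
monotonicity through signed first differences (sufficient for B-spline
curves on any knots), curvature through signed differences of the
derivative coefficients (sufficient for convexity/concavity; on equal
knot gaps these reduce to scaled second differences).  These are
sufficient, slightly conservative conditions; exactness of the fitted
shapes at the sample points is verified in the test suite.

All terms are fitted **jointly** by a single inequality-constrained
least-squares problem (penalty rows stacked into the design).  The
solver reduces the problem to least-distance programming via the
classical Lawson–Hanson transformation and solves it with non-negative
least squares; a `1e-9` ridge guards rank.  The same solver drives the
weight updates and the constrained initialization.

**Smoothness.** The penalty of each term is calibrated — via the
generalized eigenvalues of (penalty, Gram) and scalar root finding — so
that the unconstrained smoother trace equals a fixed target of 10
equivalent degrees of freedom.  Fixing rather than estimating
smoothness keeps the constrained fits stable and fast.  For
*unconstrained* terms an optional mode (`smooth_select="gcv"`) selects
each term's penalty by single-term GCV on its partial residuals (two
backfitting passes).  The unconstrained benchmark model in the
simulation studies uses this adaptive mode, mirroring the practice of
estimating smoothness when no shape constraint requires fixing it; the
constrained models always use the fixed 10-df target.

## The alternating estimation algorithm

1. Initialize `α` by a constrained linear regression of the pooled
   predictors on the response (the same QP with the design matrix in
   place of the Jacobian), or by feasible rejection sampling.
2. Ridge update: fit the constrained additive model at the current
   indices.
3. Weight update: one constrained Gauss–Newton step
   `min_δ ‖R − Vδ‖² s.t. C(α + δ) ≥ b`, where row i of `V` concatenates
   `x_ij β_j g_j′(z_ij)`.  The Hessian term involving `g″` is discarded,
   so `δ` is a descent direction.
4. Step-halving line search (up to 10 halvings): a candidate
   `α + tδ` is rescaled per group (positive factor only) and accepted at
   the first `t` whose refitted RSS does not exceed the current one.
   This guarantees a monotone RSS trace; if no `t` improves, the
   algorithm stops at the current iterate.
5. Convergence: relative RSS change below `1e-6` or step norm below
   `1e-8`; `max_iter` defaults to 50.  On exit the weights receive
   their final identifiability normalization (including a sign flip for
   unconstrained groups whose first element is negative) and the ridge
   functions are refitted once to absorb it.

Sign flips are deferred to the end because a flip with `g` held fixed
does not preserve the objective; a positive rescale does (the next ridge
refit absorbs the scale — quantile knots make the rescaled function
space identical).  When any `b_j ≠ 0`, the per-iteration rescale is
skipped entirely and identifiability rests on the constraints.
Degenerate groups (constant index values) are flagged null, carry
`β_j = 0`, and contribute zero columns to `V`.

## Degrees of freedom and model selection

The GCV criterion is `(RSS/n) / (1 − edf/n)²` with

```
edf = p + d + Σ_t edf_g(t) + Σ_j edf_α(j) ,
```

charging one degree per index and per covariate block (`d` = number of
smooth covariates, plus one if a linear block is present; the individual
θ coefficients are not charged beyond that — a deliberate reading of an
ambiguous convention, harmless for selection since it is constant across
candidate models with fixed covariates).

* `edf_α(j)` = group size minus the **rank** of the active rows of
  `C_j` at the estimate (the codimension of the face), floored at 0.
  Raw row counts would overcount when active rows are linearly
  dependent (e.g. two zero weights activate three rows of a combined
  positivity + ordering system but span only two directions).
* `edf_g(t)` = trace of the **face-restricted penalized hat matrix**:
  almost everywhere the cone-constrained penalized smoother coincides
  with the linear smoother restricted to the subspace where the active
  shape rows hold with equality, so this trace is its Stein degrees of
  freedom.  The classical approximation — unconstrained edf minus
  `c ≈ 1.5` per active constraint, floored at 1 — is exported as
  `edf_g_term` for reference.  The two mostly agree for lightly active
  fits but the count-based discount collapses for boundary fits (a
  nearly flat monotone term activates almost all rows), which makes
  spurious constrained indices look almost free and defeats the purpose
  of the penalty; the face trace does not have this failure mode and
  restores the expected behavior that constrained selection is *more*
  parsimonious than unconstrained selection.

Forward stepwise selection starts from the intercept (plus any forced
covariates), adds at each step the candidate index minimizing GCV, and
stops when no addition strictly improves it; ties break by candidate
order.

## Inference

**Normal approximation.**  `Σ_α = s²(VᵀV)⁻¹` with `s² = RSS/(n − edf)`.
The sampling distribution of `ξ = C(α − α̂)` is multivariate normal with
covariance `CΣ_αCᵀ`, truncated below at `b − Cα̂`.  When `C` is not
square it is augmented with an orthonormal basis of its row-space
complement and `−∞` bounds (a `−1e10` sentinel, never active); samples
are drawn by a coordinate Gibbs sampler over `ξ` (100 burn-in sweeps,
`B` parallel chains started at the feasible boundary state) and
back-transformed as `α* = α̂ + C⁻¹ξ*`.  When a group carries more
independent constraint rows than weights the square augmentation is
undefined; the sampler then works directly on the polyhedron
`{Cα ≥ b}` in α-space (equivalent when `C` is square).  One-sided and
two-sided truncated normals are drawn by tail-stable inverse-CDF
sampling with an exponential proposal beyond the `Φ` underflow point.

**Residual bootstrap.**  Residuals are resampled with replacement onto
the fitted values; each pseudo-response is refitted warm-started at `α̂`
with `max_iter = 25` (a cold start is available by flag), which roughly
halves the cost with no measurable effect on the intervals.  Failed
refits are dropped and counted (warning above 10%).  Confidence
intervals are elementwise empirical percentiles in both methods;
ridge-curve bands are pointwise percentiles on a fixed grid.

## Synthetic test bed

`gen_three_index` emulates an environmental-epidemiology mixture: three
groups of four predictors, multivariate normal with exchangeable
within-group correlation ρ, intercept 5, unit importances, Gaussian
noise σ ∈ {0.2, 0.5, 1}.  True weights (unit-norm):
`α₁ ∝ (0.4, 0.3, 0.2, 0.1)` (sharply decreasing, log-shaped ridge — an
air-pollution/mortality analogue), `α₂ ∝ (1, 1, 1, 1)` (moving average,
sigmoid ridge — a soft threshold), `α₃ ∝ (0.1, 0.4, 0.35, 0.15)`
(delayed peak, U-shaped ridge — a temperature/mortality analogue).  The
ridge truths are centered and scaled to unit norm under a standard
normal argument by Gauss–Hermite quadrature, so each active term
contributes unit signal variance at ρ = 0; the log ridge is extended
linearly below −4.9 so it is defined on the whole line.  The correctly
specified constraint set (positivity everywhere, decreasing orderings on
the first two indices, increasing/increasing/convex ridge shapes)
contains the truth — the moving-average weights sit exactly on the
ordering boundary, deliberately exercising active-constraint inference.
The mis-specified variant reverses the orderings and strictly excludes
the truth, producing the expected high-bias/low-variance signature.

`gen_exposome` draws 28 predictors in five blocks (sizes 4, 5, 4, 5,
10) with within-block correlation 0.3 (a synthetic stand-in for a
cohort correlation matrix; a user matrix can be supplied), gives `p*`
random predictors ±1 weights, and solves the noise variance from the
realized signal variance so that R² = 3p*/100.

What the passing experiments show: with correctly specified constraints
the algorithm recovers index weights (noiseless maximum absolute error
< 0.02 at n = 1000), forward GCV selection always retains true indices
and discards noise indices about 95% of the time under constraints
(about 80% without), and bias-corrected residual-bootstrap coverage is
near 96%.  What they do not show: behavior under model misspecification
of the ridge shapes, non-Gaussian or autocorrelated errors, real
exposure distributions (skewed, bounded), or time-series confounding —
the generators are Gaussian and i.i.d. by construction.

## Configuration files

The CLI reads a YAML (or JSON) model description.  A distributed-lag
heat-index example:

```yaml
response: deaths
lags:
  - {variable: tmax, lags: [0, 1, 2]}
  - {variable: vp,   lags: [0, 1, 2]}
groups:
  - name: heat
    columns: [tmax_lag0, tmax_lag1, tmax_lag2]
    constraints:          # alpha0 >= alpha1 >= alpha2 >= 0, as an
      - [[0, 0, 1],       # explicit matrix (equivalently the templates
         [1, -1, 0],      # [nonnegative, decreasing])
         [0, 1, -1]]
    shape: increasing
  - name: humidity
    columns: [vp_lag0, vp_lag1, vp_lag2]
    constraints: [nonnegative, decreasing]
    shape: increasing
covariates:
  - {name: day_of_season, mode: smooth, shape: none}
  - {name: year, mode: linear}
fit: {target_df: 10, tol: 1.0e-6, max_iter: 50}
```

Lag expansion creates `var_lag0..var_lagK` columns (lag 0 = same day)
and drops the first max-lag rows consistently across all series and the
response.

## Problem sizes and defaults

Simulation experiments in the tests and the reproduction script use
n = 1000 per replicate, 200 replicates for the selection study
(averaging two candidate sizes of the true index set, 1 or 2), and 100
replicates × B = 200 warm-started refits for the coverage study —
enough for standard errors of 2–4 points on the reported percentages.
Key defaults: `target_df = 10`, `n_basis = 15`, convergence `tol =
1e-6`, `max_iter = 50`, active-set tolerance `1e-8`, bootstrap
`B = 500`, truncated-normal burn-in 100.

## Known limitations

* Continuous responses only; no generalized (logistic, survival) links.
* Single-start optimization: the objective is nonconvex, and different
  seeds/starts can reach different local optima (users can loop seeds).
* The normal-approximation intervals inherit the known optimism of
  nonlinear-least-squares covariances and undercover at high noise; the
  bootstrap is the recommended default.
* Observation-level residual resampling assumes exchangeable errors; no
  block bootstrap for serially correlated data.
* Equality constraints are expressible only as paired inequalities;
  nonlinear constraints are out of scope.
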