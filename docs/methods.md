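# Methods

## Model

For sample `i` (depth `N_i`, covariate `X_i`, confounders `z_i`) and
feature `k`, the relative-abundance mean model is

```
E[Y_ik] = μ_ik = N_i · exp(β†_0k + β*_k X_i + γ_kᵀ z_i),
Var[Y_ik] = φ_k · μ_ik,
```

a quasi-Poisson specification: the dispersion `φ_k` expresses that
microbiome counts are overdispersed relative to Poisson, but it is never
estimated — every variance reported by the package is a model-robust
sandwich estimate built from empirical score contributions, so the
mean–variance proportionality is a working assumption, not a commitment.

The RA-level effect `β*_k` relates to the absolute-abundance effect by
`β*_k = β_k − β_O` with `β_O` the compositional/load effect shared by all
features; multiplicative nuisance (measurement bias `b_k`, the load
factor) is absorbed by the intercept. The latent quantities (`W_ik`,
`O_i`, `b_k`, `β_O`) have no runtime representation; only the common
shift is estimated, via the median (below).

## Estimation

**Null model (per feature).** Firth-penalized quasi-score equations over
the null design `x̃_i` = (intercept, confounders):

```
Σ_i (Y_ik − μ_ik + h_ik/2) x̃_i = 0,
```

with `h_ik` the diagonal of `H = W^{1/2}X̃(X̃ᵀWX̃)⁻¹X̃ᵀW^{1/2}`,
`W = diag(μ)`. Newton iterations with step-halving; start values
`β_0 = log((ΣY + q₀/2)/ΣN)`, other coefficients 0 — exact for the
intercept-only model, so all-zero and near-boundary features converge
immediately. Convergence: max |score| < 1e-8 or relative step < 1e-10;
at most 100 iterations, otherwise the feature is flagged and excluded
from the study's summary table (and hence from the meta-analysis set
`ℒ_k` for that study). With an intercept present the converged fit
satisfies `Σμ̃ = ΣY + q₀/2`, which the tests assert to 1e-6. Linear
solves use Cholesky factorization with a pivot-ratio condition guard
(1e12) instead of explicit inversion; rank-deficient designs raise an
error naming collinearity as the likely cause.

**Leverage convention.** The hat diagonals used in the Firth term — both
inside the null fit and inside the score statistic's residuals — come
from the *null* design. The alternative (leverages from the full design
including `X`) would make the null fit depend on the covariate of
interest and defeat the single-fit-per-feature reuse across covariate
scans. On toy cases the numerical difference is O(1/information) and is
visible in the oracle-agreement tests; the brute-force root they compare
against is accordingly defined for the quasi-score with the Firth
adjustment evaluated at the null model — the exact quantity the one-step
score expansion approximates. With that convention the first-order
agreement bound `|β̂* − β̂_full| ≤ |β̂_full|²/2` holds with margin on
two-group designs; for continuous skewed covariates at very small n the
curvature coefficient involves the μ-weighted third moment of the
adjusted covariate and can exceed 1/2, so the bound is asserted on
two-group instances (the benchmark design).

**Score statistic and sandwich.** `β̂*_k = S₁(θ̃_k)/ℐ₁` and
`V*_k = ℐ₁⁻²·Σ_i U_i²` with `U_i = r_i·(X_i − x̃_iᵀℐ₀₀⁻¹ℐ₀₁)` and
`r_i = Y_i − μ̃_i + h̃_i/2` (the Firth term stays inside the residual).
For clustered designs `Σ_i U_i²` becomes `Σ_clusters (Σ_t U_it)²`; with
singleton clusters this reduces to the independent estimator to machine
precision. No small-cluster-count degrees-of-freedom correction is
applied; with fewer than ~10 clusters the variance should not be
trusted. The estimator is exactly equivariant under affine covariate
maps and invariant to rescaling all depths; being a one-step
approximation it attenuates large effects (a two-group effect of
log-fold 1.6 is estimated near `2(R−1)/(R+1)` for group ratio `R`),
which costs a little power but not validity of the test.

**Compositional correction.** Per study and covariate,
`β̂_k = β̂*_k − m̂` with `m̂ = median_k{β̂*_k}` over exactly the features
with valid RA summaries in that study, and

```
V_k = V*_k + K / (4·(Σ_j (2π V*_j)^{−1/2})²).
```

The printed form of this calibration is ambiguous in typeset sources;
the adopted reading is the only one that reduces to the classical
asymptotic variance of a normal sample median, `πV/(2K)`, in the
equal-variance case — verified against direct Monte Carlo within 5% for
K ∈ {21, 92, 401}. The correction assumes sparse AA signals (most
features null, signs not overwhelmingly one-sided); with ~40% active
all-positive features the median is materially biased and AA effects are
systematically shifted. Below K = 20 contributing features (configurable
floor) a warning is logged.

**Meta-analysis.** Fixed-effect inverse-variance pooling over the
studies reporting each feature; association tested by
`Q = β̂²_meta/V_meta ~ χ²₁`; heterogeneity by Cochran's Q on `|ℒ_k|−1`
df (absent for single-study features). BH is applied over features,
separately for association and heterogeneity p-values and separately per
covariate. Discoveries use `q ≤ 0.05` (inclusive), heterogeneity flags
`het_q < 0.1` (strict), matching the conventional reporting thresholds;
the boundary choice is immaterial at double precision. Only a
fixed-effect model is offered.

## Synthetic data generator

`palm.simulate` emulates a multi-study spike-in benchmark without any
template-learning dependency:

- **Baselines**: per-study mean proportion vectors from normalized
  exp(Normal(0, σ)) log-abundances, σ = 2.5 by default — a few dominant
  features and a long rare tail; at K ≈ 400 typically 5–15% of features
  exceed the "relatively abundant" cut of 1e-3. Baselines are
  independent across studies (distributional heterogeneity).
- **Spike-in**: `round(π_active·K)` active features (default π = 0.1),
  half from the abundant stratum of the across-study mean baseline and
  half from its complement; fold changes Uniform(1, Δ) (default Δ = 5)
  multiply group-1 proportions for positive effects and group-0 for
  negative; both group vectors are renormalized. The AA-level truth is
  `sign·log f_k` for active features and exactly 0 otherwise, although
  renormalization shifts every feature's RA.
- **Counts**: two equal groups; per-sample composition
  Dirichlet(φ_d·μ_group) with φ_d = 50, counts Multinomial(N_i, p_i);
  depths log-normal (log-mean 9.5, log-sd 0.5, floor 2000), doubled for
  one random group under the uneven scheme.
- **Correlated samples**: within-group pairs are mixed with a fresh
  independent draw, `round((Y* + Y_it)/2)` (ties to even so counts stay
  integral), giving 2-clusters with positive within-cluster correlation.
- **Reproducibility**: all streams derive from the master seed by fixed
  offsets; the same config and seed reproduce counts bitwise, and adding
  a study leaves earlier studies' baselines and streams untouched (the
  shared active set does depend on the across-study mean baseline).

What the generator does **not** reproduce: realistic cross-feature
correlation (the Dirichlet surrogate induces only the compositional
negative dependence), cross-study persistence of feature abundance
(baselines are independent draws), and the marginal count distributions
of any real template. Rare features under a Dirichlet with tiny
concentration (φ_d·μ_k ≪ 1) are far heavier-tailed than real taxa;
analyses therefore apply the standard external 20% within-study
prevalence filter before fitting, as real-data protocols do. Passing
benchmarks on this generator demonstrates the statistical machinery
under controlled truth, not performance on any particular real cohort.

## Benchmark sizes and observed behaviour

The spike-in benchmark (tests and `scripts/acceptance.py`) uses 5
studies, K = 92, n = 100–180, balanced signs, even depths, π = 0.1,
Δ = 5, 50 replicates; the null-uniformity check accumulates ≥ 2000
feature-level meta p-values from global-null replicates of the same
layout; sandwich calibration uses 500 null features at n = 2000; effect
recovery uses 3 studies of n = 200 over 20 replicates.

Two behaviours deserve explicit mention:

- Heterogeneity is essentially never spuriously detected under
  homogeneous effects (flag fraction ~0.07% against the 2% bound).
- Empirical FDR under this surrogate generator runs mildly above the
  nominal BH level (≈ 0.06–0.08 at nominal 0.05, stable across seeds).
  Under the global null the far-tail p-values of *abundant* features are
  inflated by ~1.3–1.6× (meta z-scores have sd ≈ 1.02–1.05): the
  HC0-type sandwich is biased slightly downward at these sample sizes,
  and an abundant feature's RA effect is negatively correlated with the
  compositional median, a covariance the median-variance calibration
  ignores. Both mechanisms are inherent to the method's formulas, not to
  this implementation; the corresponding acceptance test is left failing
  rather than relaxed. Rank the q-values with this in mind when absolute
  FDR guarantees matter.

## Numerical and degenerate-input choices

- Counts must be integral; fractional values are rejected, not rounded.
- Zero-depth samples are dropped with a warning; depths are fixed from
  the full pre-filter table so prevalence filtering never changes model
  offsets; a user-supplied depth column overrides row sums.
- Prevalence thresholds are inclusive (≥) and computed within study.
- Constant covariates, covariates inside the confounder span, and
  rank-deficient designs raise typed errors; covariate scans record
  failures per (feature, covariate) pair and continue.
- The rank-based inverse normal transform uses the Blom offset
  (r − 3/8)/(n + 1/4) with mid-ranks for ties.
- Even-K medians are the midpoint of the two central order statistics.
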