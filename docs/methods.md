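# Methods

## The problem

Penalized multiple regression on biobank-scale genotype matrices — hundreds
of thousands of samples by hundreds of thousands of variants — cannot be
fitted by loading the dense matrix into memory: a 500k × 800k dosage matrix
in double precision is about a terabyte. Yet the lasso path solution is
sparse, and at any one penalty only a small fraction of variants can be
active. `basilnet` exploits this with a batch screening iterative lasso: the
data stay on disk in their native 2-bit PLINK encoding, and each outer
iteration touches the full data exactly once.

## The model

For response y, genotype matrix X (dosages of the BIM A1 allele, mean
imputed), adjustment covariates Z (age, sex, principal components, ...;
never penalized), the solver computes, over a decreasing grid
λ_1 > ... > λ_L,

    min over (γ, β) of  f(Zγ + Xβ) + λ Σ_j c_j ( α|β_j| + (1−α) β_j²/2 )

where α ∈ (0, 1] mixes lasso and ridge, c_j ≥ 0 are penalty factors, and f
is the family loss:

* **gaussian** — ½n⁻¹ Σ (y_i − η_i)², with an unpenalized intercept;
* **binomial** — n⁻¹ negative Bernoulli log-likelihood with logit link;
* **cox** — m⁻¹ negative log partial likelihood over the m observed events,
  with Breslow handling of tied event times (tied failures share the
  denominator over their common risk set). The partial likelihood is
  shift-invariant, so no intercept is fitted.

For every family the gradient of f with respect to β factors as Xᵀg for a
sample-length vector g ("gradient residual"); screening and certification
work only through |x_jᵀg|.

λ_1 is the smallest penalty at which all penalized coefficients are zero:
λ_1 = max_j |x_jᵀ g⁰| / (c_j α), with g⁰ evaluated at the unpenalized
covariate-only fit. The grid is log-equally spaced down to
λ_L = λ_1 · `lambda_min_ratio`.

## The outer loop

Each iteration has a screen / solve / check structure:

1. **Screen.** Rank all variants outside the current active set by the
   gradient magnitude |x_jᵀ g| at the last certified solution, and form the
   strong set: the ever-active variants plus the top M. This is the batch
   form of the strong screening rules — a heuristic, not a guarantee.
2. **Solve.** Materialize the strong-set columns in memory (mean-imputed)
   and fit the penalized model for the next batch of pending λ values, warm
   started from the last certified solution.
3. **Check.** One pass over the full variant universe computes the gradient
   magnitudes of every candidate solution. A candidate at λ is certified iff
   every variant outside the strong set satisfies |x_jᵀ g(λ)| / c_j <
   λα(1 + tol) — the KKT stationarity condition that licenses setting those
   coefficients to exactly zero. Scanning down the batch, certification
   stops at the first failure; certified solutions are exact full-universe
   solutions. If the entire batch fails, the engine falls back to the last
   certified λ and enlarges M by ΔM, which guarantees termination: the
   strong set grows monotonically toward the full universe, where the
   condition holds vacuously.

The checking pass doubles as the next iteration's screening pass, so the
number of full-data scans equals the number of outer iterations (an
instrumented counter asserts this). A one-off preparatory scan computes the
per-variant QC statistics and imputation means before the loop starts.

Certified solutions are independent of M and ΔM up to solver tolerance; the
test suite asserts bit-level agreement across M ∈ {10, 100, 1000} and
adversarial M = ΔM = 1.

## The inner solver

The strong-set subproblem is solved by cyclic coordinate descent with an
active-set strategy, followed by a *support polish*: once the support and
signs are stable, the stationarity system restricted to the support is a
small dense linear system and is solved exactly, then the full in-memory
KKT residual is verified (violators re-enter coordinate descent). This
yields stationarity at essentially float resolution and is much faster than
iterating coordinate updates to convergence on ill-conditioned saturated
fits. A tie guard of 1e-12 (relative) in the soft-threshold comparison
keeps variables whose gradient sits exactly at the threshold — notably the
argmax variant at λ_1 — at exactly zero despite float roundoff in the
working response.

Binomial and Cox losses are handled by an outer quadratic approximation:
iteratively reweighted least squares around the current linear predictor
(weights p(1−p)/n for the binomial; the diagonal of the Breslow Hessian for
Cox), with step halving whenever the penalized objective would increase.
The binomial iteration is a proximal Newton method with the exact Hessian
diagonal and converges quadratically; the loop exits on stationarity of the
true problem at 1e-9 relative. The Cox Hessian has substantial off-diagonal
mass and its diagonal surrogate converges only linearly along near-flat
directions of the partial likelihood, so Cox fits finish with an
accelerated proximal-gradient refinement (FISTA with backtracking and
adaptive restart, up to 600 iterations) on the true objective.

Numerical defaults: coordinate-descent convergence at max |Δβ| ≤ 1e-7 ×
max(1, max|y|) per sweep, at most 10,000 sweeps per λ; 50 outer
quadratic-approximation iterations (20 for Cox); KKT certification
tolerance 1e-6 relative to λα. Screening ties break by ascending variant
index. Variants are *not* standardized by default: dosages already share
the 0–2 scale, and dividing by per-variant standard deviations would
effectively relax the penalty on rare variants and invite spurious
selections.

Near the saturated end of a path with p > n the design restricted to the
active set approaches singularity and, for Cox, the partial likelihood
becomes nearly flat; coefficient identification degrades there for any
solver. The defaults stop the grid before that regime
(`lambda_min_ratio` 0.01 when p > n, 1e-4 otherwise, and 0.1 for Cox), and
validation-based early stopping usually ends the path earlier still.

## Data handling

PLINK 1 .bed files are memory-mapped and decoded through a 256 × 4 lookup
table (bit pairs from the least-significant end: 00 → dosage 2, 01 →
missing, 10 → 1, 11 → 0; dosages count the A1 allele). QC keeps variants
with missing rate ≤ 10% and minor allele frequency ≥ 0.1%. Missing
genotypes are mean-imputed; statistics and imputation means are computed on
the *training* split only and reused for validation/test predictions, so no
information leaks across the split (training-mean reuse is this package's
choice where conventions differ). The screening/checking kernel exploits
the four-level dosage alphabet: xᵀr = 1·Σ_{x=1} r + 2·Σ_{x=2} r +
μ·Σ_{x=missing} r, skipping the ~70% zero entries, and serves all residual
columns of an iteration in one sequential variant-major pass.

Survival input convention: `event=True` means the failure was observed;
sources coding censoring as an indicator that is 0 at failure must be
inverted at ingestion.

## Model selection and variants

With a validation split, R² (gaussian) or AUC (binomial) is computed for
every certified λ, and the run stops once the metric has gone
`early_stop_patience` (default 2) certified λ values without improving on
its running best. The metrics module defines only R² and AUC; for Cox the
engine uses the negative validation partial likelihood as the selection
score (the concordance index is out of scope). AUC is computed as the exact
Mann–Whitney rank statistic with half-credit for ties — identical to the
area under the ROC curve, cheaper and tie-exact.

The relaxed lasso refit — an unpenalized refit on the active set, with the
adjustment covariates kept in the design — is available per certified λ
(`relaxed=True`) to undo shrinkage bias. The batch-size heuristic sets the
initial M to the number of variants whose initial gradient magnitude
exceeds 2λ_target − λ_1 (strong-rule coverage of the first ~10 λ values),
floored at `min_batch` (default 1000, capped at p).

## The synthetic generator

The generator emulates a biobank fileset at desk scale: biallelic hard
calls Binomial(2, MAF) with MAF uniform on [0.05, 0.5] by default, i.i.d.
missingness (default 1%), and a sparse causal signal. Gaussian traits set
the noise variance so the genetic share of var(y) equals the requested
heritability; binomial traits scale the latent effects against the logistic
variance π²/3; Cox times are exponential with rate h₀·exp(η) and
independent exponential censoring whose rate is solved (Brent) to hit the
requested censored fraction. Splits default to 60/20/20
train/validation/test, seeded. An optional block-autoregressive mode adds
within-block LD to exercise the elastic net's grouped-selection behaviour.

What the generator does *not* emulate: realistic LD from recombination,
population structure and relatedness, genotyping batch effects,
variant-call error, or imputed (non-hard-call) dosages. Tests passing on
these fixtures therefore certify the *algorithm* — exactness of the
screened path, format round trips, gradient correctness — not robustness to
the confounding structure of real cohort data, which is what the adjustment
covariates are for.

Default study conditions used by the test suite and the acceptance script:
the Gaussian exactness problem is n = 400, p = 1000 with 20 causal variants
and h² = 0.6; the binomial/elastic-net problem is n = 600, p = 1500 with 50
path points; the recovery problem is n = 2000, p = 5000, 10 causal
variants, h² = 0.8. These sizes are chosen so each full run exercises
several outer iterations (the strong set is rebuilt and certified many
times) while a direct full-matrix oracle fit remains computable for
comparison.

## Known limitations

* Pure ridge (α = 0) is excluded; the λ grid and screening rules assume
  α > 0.
* No cross-validation — model selection follows the fixed
  train/validation/test design.
* Cox: Breslow ties only (no Efron), no baseline-hazard estimation, no
  stratification; path precision at very small λ is limited by the
  flatness of the partial likelihood (see above).
* Sample weights and coefficient bounds are not implemented (contract
  extension points).
* PLINK 2 .pgen and sample-major .bed files are not read.
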