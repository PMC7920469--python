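# Methods

## The selection problem

Given n observations of p correlated variables and an outcome — continuous
(linear model) or binary (logistic model) — the goal is to estimate the
active set S* = {j : beta_j != 0} while controlling the false discovery rate

    FDR = E[ |S_hat \ S*| / max(|S_hat|, 1) ] <= q.

The motivating application is microbiome association analysis: log-transformed
taxon abundances are high-dimensional, strongly correlated, and zero-inflated,
and the number of truly associated taxa is assumed small, so an uncorrected
sparse fit risks many spurious selections.

## Gaussian knockoffs

Rows x_i of the design are modeled as N(0, Sigma) with Sigma positive
definite. A knockoff copy is sampled conditionally,

    x~_i | x_i ~ N(x_i - x_i Sigma^{-1} diag{a},
                   2 diag{a} - diag{a} Sigma^{-1} diag{a}),

with a positive vector `a` chosen so the conditional covariance V is positive
definite. Jointly, [X X~] has covariance [[Sigma, Sigma - diag{a}],
[Sigma - diag{a}, Sigma]]: knockoffs reproduce the correlation structure of
the originals while being conditionally independent of the outcome, so a null
variable and its knockoff are exchangeable.

Choices made where the construction is under-determined:

- **s-vector.** Default is the closed-form equicorrelated choice
  a_j = min(2 lambda_min(Sigma), min_j Sigma_jj), shrunk by a relative slack
  of 1e-6 to keep V strictly definite. An SDP variant (maximize sum(a)
  subject to the joint covariance staying PSD) is implemented behind an
  optional convex-solver import and falls back to the equicorrelated choice
  with a warning when no solver is installed. The equicorrelated form is
  solver-free and standard.
- **Unknown Sigma.** Simulations use the true Sigma. For data, the default is
  Ledoit-Wolf analytic shrinkage toward a scaled identity
  (`estimate_covariance(..., "shrinkage")`), which stays positive definite
  even with p near or above n; the plain sample covariance is available but
  can be singular there.
- **Standardization.** Data-mode pipelines center columns and scale them to
  unit variance before knockoff construction and path fitting (penalized
  paths are scale-sensitive), so the covariance is estimated on the
  correlation scale. Simulations, which draw columns at unit variance by
  construction, use the raw draws.
- **Numerical definiteness.** Matrices are symmetrized and required to have
  minimum eigenvalue >= 1e-8.

## Path statistics

On the augmented design [X X~] the entry value Z_j is the largest penalty at
which coefficient j is nonzero in the l1-penalized fit, and

    W_j = max(Z_j, Z~_j) * sign(Z_j - Z~_j),     sign(0) = 0.

- **Linear loss.** The least-angle implementation of the lasso path gives the
  exact piecewise-linear solution path; entry values are read off the path
  knots, so there are no grid artifacts. The outcome is centered and no
  intercept is fit. The penalty is reported on the scale where the path
  starts at max_j |x_j' y|.
- **Logistic loss.** No exact path exists, so a log-spaced descending grid of
  100 penalties (50 in the reduced-scale benchmarks; configurable) spans
  [tau_max * 1e-3, tau_max], where tau_max = max_j |x_j'(y - ybar)| is the
  smallest penalty with an all-zero solution, computable from the null-model
  gradient. Each grid point is fit with liblinear's l1 solver; the intercept
  is made effectively unpenalized via a large intercept scaling. Z_j is the
  largest grid penalty with a nonzero coefficient; the grid-refinement
  property test checks entry values move by less than one grid step when the
  density doubles.
- **Ties and tolerances.** A coefficient counts as nonzero above 1e-8.
  Z_j = Z~_j gives W_j = 0, and zero W values are excluded from the
  threshold's candidate set, so exact ties are never selected (conservative).

## Thresholds

For target level q the threshold scans the positive magnitudes
t in {|W_j| : W_j != 0} in increasing order and returns the smallest t with

    (#{j : W_j <= -t} + offset) / max(#{j : W_j >= t}, 1) <= q,

offset 0 for the standard knockoff filter (approximate FDR control) and 1 for
knockoff+ (exact finite-sample control). No qualifying t means an empty
selection (threshold +inf), not an error. A consequence worth keeping in mind
when interpreting results: knockoff+ at level q cannot return fewer than
ceil(1/q) selections, so with very sparse signals and small q it frequently
returns none.

## Aggregation

The filter is run k times (default k = 5, a compute/effect trade-off), run i
at level q_i, each run on a fresh knockoff draw from a deterministically
derived child seed, and the selections are united. Two schedules:

- **geometric** (default): q_i = q / 2^{i-1}. Sums to q(2 - 2^{1-k}) > q for
  k >= 2; works well empirically.
- **strict**: the same halving sequence rescaled to sum to q exactly. Since
  each knockoff+ run controls its own FDR at q_i and the union's false-
  discovery ratio is subadditive across runs, the union controls FDR at
  sum q_i = q. This is the schedule to use when the certified bound matters,
  and the one the acceptance benchmarks measure.

With k = 1 either schedule reduces the scheme to the plain filter exactly
(same derived seed, same threshold, same set — tested). A `shared_knockoffs`
ablation reuses one knockoff draw across runs; the FDR bound is unaffected,
but fresh draws are the default since independent randomizations are what the
aggregation is meant to stabilize.

## Simulation benchmark

Reference conditions: n = 200 observations, p = 100 variables, AR(1)
covariance Sigma_ij = 0.5^|i-j|, 20 coefficients set to 1 at uniformly random
positions and rescaled so ||X beta||^2 / (n sigma^2) = 5 with sigma^2 = 1;
linear outcomes y = X beta + N(0, sigma^2 I) or logistic outcomes
y_i ~ Bernoulli(expit(x_i' beta)). The headline linear experiment uses 100
repetitions; the logistic one uses 30 repetitions with a 50-point penalty
grid, problem sizes chosen to keep a full run at desk scale. Per repetition,
k knockoff draws and their W statistics are shared across every method and
threshold variant, so KO-vs-AKO comparisons are paired on identical data; a
by-product of the halving schedule is that the single-run filter is exactly
the first aggregation run, making the union's power dominance pointwise.

Power is reported as the true-positive proportion |S_hat ∩ S*| / |S*|. (The
complement-of-FDP variant that divides by |S_hat| instead is available via
`paper_denominator=True` for comparability with texts that define power that
way, but it is redundant with FDP and not the default.) Empirical FDR is the
mean FDP across repetitions with its standard error; the acceptance checks
require mean FDP <= q + 3 SE for knockoff+ aggregation under the strict
schedule.

Default level grid for sweeps: {0.05, 0.1, 0.15, 0.2, 0.25, 0.3}. Degenerate
logistic repetitions (single-class outcomes, rare at these settings) are
regenerated once, then skipped and counted.

## Microbiome pipeline

Count tables (samples x taxa) are optionally converted to per-sample relative
abundances (default on), zeros are replaced by 0.5 times the minimum observed
positive abundance — globally by default; a per-taxon variant exists and
errors on all-zero taxa — and the natural log is applied. The transform is
single-shot; the pipeline applies it exactly once. Log base and the global
pseudo-count convention only shift/scale columns, which the subsequent
standardization absorbs.

BMI is classed as underweight (< 18.5), normal ([18.5, 25)), overweight
([25, 30)), obese (>= 30 kg/m^2); the half-open boundaries follow the
standard convention, with >= 30 defining the obese outcome y = 1. Seven
groupings of classes (all, uw+ob, nor+ob, ow+ob, uw+nor+ob, uw+ow+ob,
nor+ow+ob) restrict the sample before the logistic-knockoff selection, and
selected column indices map back to taxon names in the report.

### Synthetic cohort generator

Real cohort abundance data are not shipped, so `generate_synthetic_counts`
emulates their qualitative features: latent log-abundances drawn from an
AR(1) Gaussian (rho = 0.5 by default) to mimic inter-taxon correlation,
exponentiated, shifted, and rounded to counts, then thinned to a target zero
fraction (default 0.3) by zeroing the smallest entries. Obesity labels follow
a logistic model on the standardized preprocessed signal taxa (default 5
signal taxa out of p = 50, slope effect_size / sqrt(n_signal) per taxon with
effect_size = 2.0, a clearly detectable but not deterministic association);
BMI values are then drawn uniformly within the weight class consistent with
each label (non-obese samples split 10/60/30 across uw/nor/ow, roughly the
composition of an adult cohort). Defaults use n = 200 samples.

What the generator does *not* emulate: compositional closure effects beyond
simple row normalization, taxon-specific dispersion, sequencing-depth
variation across samples, and phylogenetic correlation structure. Passing
error-control checks on this generator therefore demonstrates the pipeline's
correctness under its stated Gaussian-latent assumptions, not performance on
any particular real cohort.

## Known limitations

- Gaussian-design knockoffs only; heavy-tailed or discrete designs violate
  the sampling assumption (log abundances after preprocessing are treated as
  approximately Gaussian).
- With an estimated (shrinkage) covariance the exchangeability, and hence the
  FDR guarantee, is approximate.
- The knockoff+ granularity floor (>= ceil(1/q) selections or none) makes the
  procedure conservative to the point of emptiness when the true support is
  much smaller than 1/q — visible on the synthetic microbiome cohorts with 5
  signal taxa at q = 0.1, where most tables yield no selections at all.
- Logistic entry values inherit the grid resolution; the default grids make
  this error smaller than one multiplicative grid step.
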