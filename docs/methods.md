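# Methods

This note documents the models, the numerical choices and the synthetic
benchmark behind `matcher`, at the level of detail a user needs to judge
what the package's results do and do not show.

## Pseudotime: one-dimensional Bayesian GPLVM

Each modality's observation matrix Y (n cells × d features) is standardized
per feature to zero mean and unit variance before fitting; zero-variance
features are dropped with a logged warning. Standardization makes the RBF
amplitude interpretable across modalities and gives the generative model a
well-defined zero prior mean to revert to far from the data. A matrix whose
features are all constant is rejected as degenerate.

The model places a GP prior with squared-exponential kernel
k(tᵢ, tⱼ) = σ²_rbf exp(−(tᵢ−tⱼ)²/(2l²)) on the latent-to-feature maps, a
standard normal prior on the scalar latent t per cell, and i.i.d. Gaussian
observation noise σ². Inference maximizes the collapsed variational lower
bound (Titsias & Lawrence) built from the kernel expectations Ψ₀, Ψ₁, Ψ₂ of
the Gaussian variational posterior q(tₙ) = N(μₙ, sₙ) and m inducing inputs.
Gradients of the bound with respect to every parameter (μ, s, inducing
inputs, σ²_rbf, l², σ²) are computed analytically; the test suite checks
them against central finite differences at relative tolerance 1e-5.

Defaults and their reasons:

- **Inducing inputs: m = 10**, initialized at evenly spaced quantiles of
  the initial latent values. Accuracy on the synthetic benchmark changes by
  less than 0.05 between 10 and 20 inducing inputs (tested).
- **Initialization:** PCA scores of the standardized matrix (concatenated
  matrices for the shared model), scaled to unit variance; sₙ = 0.5;
  σ²_rbf = 1, l = 1 (the latent scale), σ² = 0.1.
- **Restarts: 3** — the PCA start plus two seeded perturbations
  (latent + 0.2·N(0,1), log-hyperparameters + 0.3·N(0,1)); the fit with the
  best final bound is kept. The variational objective is multimodal and a
  single start occasionally lands in a visibly worse optimum.
- **Optimizer:** L-BFGS-B on log-transformed positive parameters
  (memory 40, iteration cap 3000, ftol 1e-12). The schedule is two-stage:
  the noise variances are pinned at their initial value for a first pass of
  up to 500 iterations, then everything is freed and the optimizer is
  re-invoked until the bound stops improving (relative 1e-7, at most 4
  rounds). The first stage prevents the noise variance from collapsing
  before the latent arrangement is settled; the re-invocations recover from
  line-search stalls that L-BFGS hits on stiff low-noise problems. On
  noiseless data this schedule is the difference between rank correlation
  ≈ 0.97 and ≈ 1.0 with the generating order.
- **Numerical conditioning:** the inducing-point Gram matrix carries a
  fixed relative nugget 1e-6·σ²_rbf on its diagonal. A state-dependent
  (adaptive) jitter is deliberately *not* used inside the objective: jitter
  that switches levels with the parameters makes the objective
  discontinuous and reliably breaks the quasi-Newton line search. An
  adaptive Cholesky ladder (1e-8 up to 1e-2) remains only as a last-resort
  fallback outside the hot path.
- **Hyperparameter bounds:** log-scale box constraints (e^−12, e^12) for
  the kernel parameters and (e^−12, e^8) for the variational variances,
  wide enough never to bind in practice while keeping the optimizer out of
  non-finite territory.

The latent sign is not identifiable and is left untouched by the fit;
orientation is resolved downstream (below). The posterior predictive mean
and variance at arbitrary latent positions use the optimal variational
distribution over the inducing outputs; predictions revert to the zero
prior mean (on the standardized scale) a few lengthscales outside the
trained latent range, and are de-standardized to original units where the
application calls for it (correspondence generation).

The shared-latent variant for simultaneously measured modalities ties one
q(t) across views; each view keeps its own kernel hyperparameters and
inducing inputs, and the data terms of all views are summed with a single
KL penalty. It requires identical cell IDs in identical order and refuses
anything else, listing the symmetric difference.

## Orientation

The direction of pseudotime cannot be inferred from data, so it must come
from prior knowledge: either an explicit `keep`/`reverse` per modality or a
declared marker, `marker:<feature>:<increasing|decreasing>`. The marker
rule reverses the latent iff the sign of Spearman(latent, marker)
contradicts the declared direction, and refuses to guess when
|Spearman| < 0.1 ("uninformative marker"). The refusal threshold is a
guard against silently wrong global orientation, the one error that flips
every downstream sign.

## Warping to master time

Master time is defined so that the population of cells is uniform on
[0, 1]. The warping function is learned by aligning sample quantiles of
(normalized) pseudotime — the independent coordinate — with the theoretical
uniform quantiles — the dependent coordinate. Choices:

- **50 quantile levels**, evenly spaced *including* 0 and 1, so the extreme
  anchors pin warp(min) = 0 and warp(max) = 1 exactly. Master-time vectors
  from 25/50/100 quantiles correlate above 0.99.
- **Sample quantiles** use the common linear-interpolation estimator.
- **Smoother:** GP regression (constant × RBF + white kernel, hyperparameters
  by marginal likelihood) on the anchor pairs. The white-noise level is
  capped at 1e-4 because the anchors are near-noiseless quantiles; the GP
  should closely interpolate them, not smooth through them. The GP mean is
  tabulated on a 1000-point grid, affinely rescaled to pin the endpoint
  anchors at exactly 0 and 1 (a positive affine map, so monotonicity is
  unaffected), and checked for monotonicity: any first difference below
  −1e-9 triggers the **linear-interpolation fallback**, which is monotone by
  construction because the anchors are. The method actually used is
  recorded on the warp object.
- **Ties** in pseudotime collapse to a single anchor with the mean master
  value of the tie group, so tied inputs always receive identical master
  times.
- **Extrapolation clamps**: inputs below/above the anchor range map to 0/1.
  Master time is bounded by construction; extrapolating a smoother outside
  its anchors has no meaning here.
- The **inverse** warp is piecewise-linear inversion of the tabulated
  forward map and is only defined on [0, 1].

## Correspondence generation and correlation

To generate the measurement a source cell would have produced in a target
modality: source master time → inverse target warp → target (normalized)
pseudotime → affine map back to the target's latent scale (undoing the
target's orientation and normalization) → target GPLVM posterior
predictive mean, de-standardized to original units. The predictive mean is
used rather than a posterior draw because it is deterministic and
testable; predictive variances are returned alongside.

Cross-modality feature correlation correlates *observed* source features
with *generated* target features over the source cells; Spearman by
default, since monotone nonlinear relationships are expected. Zero-variance
features yield NaN entries, never a silent 0.

## Decoupling test

Given master times m₁, m₂ for the same cells, the cells are split by
thresholding m₁ at a split point (default 0.3). The Pearson correlations
r_before, r_after between m₁ and m₂ in the two groups are compared with
Fisher's r-to-z: z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)), one
tailed against H0: r_before ≤ r_after. Correlations are clamped to
±(1−1e-15) so two perfectly correlated groups compare as z = 0. The
companion permutation test redraws ⌊0.3n⌋-vs-rest splits (the observed
statistic and the permuted ones are Spearman differences, mirroring the
asymmetry of the original analysis rather than harmonizing it), and
reports the add-one estimator p = (1 + #{perm ≥ observed})/(1 + n_perm),
which can never return an exact zero. Both master-time vectors (not raw
pseudotimes) feed the test; the threshold groups must have ≥ 4 cells each,
while the permutation group size is ⌊0.3n⌋ by design. A split-scan utility
reruns the test at alternate split points.

## Lagging cells

With ordered experimental time points, a cell lags iff its master time is
≤ the maximum master time among cells of the *immediately preceding* time
point; the first time point never lags. Only the adjacent earlier time
point is consulted, matching the per-time-point maxima this call is read
against.

## Preprocessing formulas

- ATAC-style counts are binarized (count > 0 → 1) to dodge copy-number and
  repeat artifacts, aggregated by summing member peaks per group (a peak in
  several groups contributes to each), cells with fewer than 1000 detected
  events are removed (the cutoff is strict: exactly 1000 is kept), and each
  cell j is scaled by s_j = (Σ t_j / n)/(1000·t_j) with t_j the cell's
  detected-event total — after which every cell's scaled total equals the
  mean total / 1000 exactly.
- Histone-mark signature matrices are scaled by s_j = 10·(Σ t_j / n)/t_j,
  where t_j is the cell's aggregated-signature total (the aggregated rather
  than raw total, since only the aggregated matrix is available at this
  stage).
- Methylation sites are selected by Pearson correlation ≥ 0.2 with a
  validated marker site; the marker itself is always retained.
- Expression signatures from named gene lists: genes on more than one list
  are dropped entirely; remaining genes are z-scored across cells; each
  cell gets a per-list sum of member z-scores and a total sum over all
  z-scored genes; the signature is the across-cell z-score of
  (list sum − total sum). The subtraction is the literal reading of
  "difference of the sums"; residualization would be the alternative
  reading and is not what this implements.
- A generic latent-outlier utility drops cells beyond k MADs (default 5)
  from the median of a pilot single-restart GPLVM latent; manual outlier
  removal by inspection is not reproducible, this is the programmatic
  stand-in. A plain per-gene variance top-k filter stands in for
  trajectory-aware gene selection done by external tools.

## Synthetic benchmark

The generator draws master time uniform(0, 1) per cell, maps it through a
monotone warp (families: identity, `power:a`, `beta_cdf:α,β`; default
`power:2`), and generates each feature as a logistic sigmoid of pseudotime
with center ~ U(0.1, 0.9), slope ~ U(4, 12), random sign, and amplitude
scaled so the noiseless range over pseudotime ∈ [0, 1] is exactly
`feature_range` (default 16). Gaussian noise with standard deviation
`noise_sigma` (default 9 — 56% of the range) is added. Defaults are 100
cells and 600 features. Sigmoids were chosen as the feature family because
they are smooth, monotone per feature and representable by the RBF GP;
the warp default is a genuinely curved monotone map rather than the
identity. All draws flow from one seed.

Paired simulations share a single master-time draw between two modalities
with separate warps, feature sets and noise, optionally keeping disjoint
random cell subsets per modality; the generating cell matching and
per-pair "true-correspondence" correlations (generating functions plus
modality noise evaluated on the full shared draw) are returned as oracles.

What the simulator does *not* emulate: count noise, dropout and
zero-inflation, batch effects, branching trajectories, and features that
are non-monotone in pseudotime. Passing the benchmark therefore
demonstrates correct inference under the model's own assumptions — a
one-dimensional monotone process with smooth feature responses — not
robustness to the full pathology of real single-cell data.

Benchmark scales used by the test suite and acceptance script: the
headline accuracy run is 100 cells × 600 features × 10 replicates; the
correlation-inference benchmark uses 50-cell disjoint halves, noise at 25%
of the feature range, and 50 random feature pairs; unit tests run smaller
(40–120 cells, 20–100 features) with a single restart. These sizes were
chosen as the smallest at which the measured quantities are stable.

## Determinism

One `RunConfig.seed` drives everything; per-step sub-seeds are derived by
an FNV-style hash of a step label, so adding a step never shifts another
step's stream. Reruns with identical config and inputs are byte-identical
in every output table and serialized model (verified in the suite).
Serialization is JSON text throughout.

## Known limitations

- One-dimensional, non-branching trajectories only; cyclic or
  back-and-forth processes violate the model's monotonicity assumption.
- Orientation requires prior knowledge; there is no data-driven fallback
  by design.
- The inducing-point approximation (m = 10) limits resolution of structure
  much finer than the typical inducing spacing; heavily compressed regions
  of pseudotime (severe warps) are ordered slightly less reliably.
- The GP warp smoother can fail monotonicity on clustered pseudotime and
  falls back to interpolation; with fewer distinct pseudotime values than
  quantile anchors the warp is still valid but anchors contain ties (a
  warning is emitted).
- Fisher's r-to-z assumes bivariate normality within groups; the
  permutation test is the more defensible of the two p values for master
  times, which are by construction uniform.
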