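# Methods

## Model and assumptions

Each of N entity profiles `x_i` (length M, real-valued, typically
log-ratios) is assumed to be generated by one of an unbounded number of
mixture components. The component mean is a piecewise linear sequence
(PLS) over a *fixed, user-chosen* segmentation of the M time points into
S contiguous segments: the parameter vector
`mu = (init, slope_1, jump_2, slope_2, ..., jump_S, slope_S)` (L = 2S
entries) is mapped to per-time-point means by the design matrix C, where
row m (time t_m, inside segment s) evaluates

```
init + sum_{r=2..s} jump_r + sum_{r=1..s-1} slope_r (t_end(r) - t_start(r))
     + slope_s (t_m - t_start(s)).
```

Slopes multiply real time offsets, so unequal sampling is respected.
Columns of C that are identically zero (the slope of a single-time-point
segment) are pruned to keep C full column rank; `column_map` records what
remains. Noise is isotropic Gaussian with a per-component precision
`lambda_k ~ Gamma(a, b)` (shape/rate), the PLS parameters have a diagonal
Gaussian prior with variances `V_init, V_jump, V_slope` (default 100
each — effectively flat against typical log-ratio scales), and the
partition follows a two-parameter Chinese restaurant process
(concentration `alpha`, discount `d`), i.e. a Pitman-Yor prior. Key
assumptions: segments are shared by all components, noise is independent
across time points given the component, and the partition is
exchangeable.

## Temporal segmentation (CONF)

Time points are clustered by average-linkage agglomerative clustering of
their N-vectors of values using Euclidean distance (the natural reading
of a "Gaussian" pairwise distance; no formula-level convention exists for
this step, and raw rather than standardized values are used). The
dendrogram is cut at a user threshold: merges with height strictly below
the threshold are accepted, so threshold 0 yields all singletons. Because
unconstrained clustering can group non-adjacent time points while a PLS
segment must be contiguous in time, each group is split into maximal runs
of consecutive indices. A sweep mode lists the segmentation at every
distinct merge height, replacing interactive dendrogram inspection.
Segmentation is deliberately *not* inferred: it is the user's statement
about the experimental design.

## Collapsed MCMC (INF)

`mu_k` is never sampled. Every likelihood evaluation uses the exact
Gaussian integral: for a component with n members, sum vector s and
squared norm ss,

```
log p(X | lambda) = (nM/2) log(lambda/2pi) - (lambda/2) ss
                  - (1/2) log|Sigma_mu| - (1/2) log|A| + (1/2) b' A^{-1} b,
A = Sigma_mu^{-1} + lambda n C'C,   b = lambda C' s,
```

an L-dimensional Cholesky solve rather than the dense nM-dimensional
covariance (the two are algebraically identical; the dense form is kept
as a test oracle). The posterior predictive for one profile is
`N(x; C m_k, C S_k C' + lambda^{-1} I)` with `S_k = A^{-1}`,
`m_k = lambda S_k C' s`.

One iteration applies three moves:

1. **Precisions.** For each component, 3 Metropolis-Hastings steps with a
   log-normal random walk (scale 0.5) targeting the Gamma prior times the
   collapsed likelihood; the log-scale Jacobian `lambda'/lambda` enters
   the acceptance ratio.
2. **Assignments.** A collapsed Gibbs sweep in entity order. Existing
   components weight `(n_k - d) * predictive`; a new component weights
   `(alpha + d K)/n_aux * sum_u predictive(lambda_u)` over `n_aux = 3`
   auxiliary precisions drawn fresh from Gamma(a, b) (an algorithm-8
   style auxiliary-variable scheme; the chosen auxiliary precision
   instantiates the new component). All weight arithmetic is in log
   space with log-sum-exp normalization.
3. **Hyper-parameters.** MH updates of a, b (log scale, scale 0.5) and
   alpha (log scale), d (logit scale, scale 0.3) against the
   non-informative priors 1/alpha, 1/d, 1 and b. The prior proportional
   to *b* is unusual for a rate parameter but is implemented literally;
   `ChainConfig(b_prior="reciprocal")` selects the conventional 1/b
   instead. Proposals whose log target is non-finite are rejected
   outright, which also guards the improper 1/d prior near d = 0.

Defaults: 20 chains × 10 000 iterations, 2500 burn-in, initial
a = 2.1, b = 0.24, d = 0.001, alpha = 100. Each chain starts from a
single all-inclusive component with `lambda_1 ~ Gamma(a, b)` — at
N ≈ 3000 a singleton start mixes much more slowly. Iterations with index
strictly greater than the skip value contribute the indicator
`[z_i = z_j]` to the similarity counts; chains are equally weighted, so
every off-diagonal similarity is an integer multiple of 1/(total
retained samples). All randomness flows from a single seed through a
per-chain derivation, making runs bit-for-bit reproducible.

MH proposal families, step counts (3 per update) and the initialization
are this package's own choices; acceptance rates for every family are
reported as a tuning diagnostic.

## Two-stage clustering (CLUS)

Stage 1 merges from singletons under complete linkage on *similarity*
(link = minimum pairwise similarity across the two clusters), merging
the best pair while its link ≥ m. Stage 2 repeatedly extends the
(cluster, outside entity) pair with the best affinity
(min member similarity) while ≥ e; entities in other clusters stay
candidates, which produces overlap. Comparisons are strict as stated
("stop when smaller than the threshold"), so m = 0 produces one cluster
and e = 0 lets every cluster absorb everything. Because similarity
values tie in practice (they are multiples of 1/n_retained), ties are
broken lexicographically by smallest member indices — this is what makes
the output deterministic. Duplicate clusters created by extension are
dropped. Internal quality is summarized by the Davies-Bouldin index
(centroid = mean member profile, scatter = mean distance to centroid)
plus mean intra- and inter-cluster pairwise profile distances.

## Enrichment (EVAL)

OBO 1.2 ontologies are parsed with `obonet`, GAF 2.0 annotations with
Biopython's GAF reader (both behind light validation that reports line
numbers). Direct annotations are propagated along `is_a` and `part_of`
to all ancestors; obsolete terms are kept but excluded from propagation;
secondary ids resolve through `alt_id`. Dataset identifiers match
annotations case-insensitively by object id, then symbol, then synonym.
The background is the set of dataset identifiers with at least one
propagated annotation (a genome-wide background is available via
`background="annotation"`; the definition of "total number of unique
genes" is ambiguous, so both are provided). For each cluster with ≥ 2
members, every term annotating ≥ 1 member is a hypothesis; the p-value
is the upper hypergeometric tail computed via stable log-gamma routines
(scipy), and correction (Bonferroni default, BH optional) is applied per
cluster across all three namespaces jointly (`family="global"` spans
clusters instead — which family the original formulation intended is
unclear, and per-cluster is the more conservative reading for reporting
per-cluster term lists). Significance means adjusted p < alpha
(default 0.01). NOT-qualified annotation rows are excluded; evidence
codes are not filtered.

## Synthetic data

The generator runs the model forward: given a design model, per-cluster
PLS vectors and precisions, it emits `x_i = C mu_{z_i} + noise`. The
default operating point — 3 clusters × 20 entities, the two-segment
8-time-point design with unequal stamps (0–120 min), noise SD 0.2
(lambda = 25), and cluster mean profiles drawn at scale 2 and re-drawn
until every pair is ≥ 3 noise SD apart in RMS per time point — is small
enough for minutes-scale MCMC yet genuinely separable, so recovery
failures indicate sampler or clustering defects rather than an
impossible task. A larger 15-point, 7-segment design
(`glu_like_model()`) mirrors a dense-early/sparse-late perturbation
time-course. The GO fixture generator plants one term annotating exactly
a known gene subset, giving an analytically known hypergeometric
p-value, and exercises both propagation relations. What the generator
does **not** emulate: platform noise (dye bias, count overdispersion),
missing values, replicate structure, or correlated noise across time —
so passing recovery tests demonstrate correctness of the inference
machinery, not robustness to real-data artifacts.

## Numerical choices and problem sizes

Cholesky factorizations for all L-dimensional solves; an
eigendecomposition of `C Sigma_mu C'` precomputed per run makes
empty-component predictive evaluations O(M) per auxiliary draw;
per-component predictive caches are invalidated on membership or
precision changes. Degenerate inputs: empty weight vectors cannot occur
(the new-component weight is always finite); all-zero similarity rows
simply never merge; a single cluster reports no Davies-Bouldin index.

The test suite and the acceptance script run the sampler at reduced,
seconds-to-minutes scales chosen as the smallest sizes at which each
property is informative: exact oracles on stacked dimension ≤ 12,
sampler calibration on a 2-entity problem with 50 000 iterations
(batch-means standard errors absorb autocorrelation), and recovery on
60 entities with 2 chains × 2000 iterations over ten seeds. The
default 20 × 10 000 configuration is intended for real datasets of
hundreds to thousands of entities.

## Known limitations

- The segmentation is trusted, not inferred; a wrong segmentation biases
  every downstream phase.
- The literal prior ∝ b on the Gamma rate is improper and increasing;
  with few components the b-chain can drift. The reciprocal option is
  provided.
- The 1/d prior concentrates mass at d → 0; d effectively behaves as a
  small perturbation of a Dirichlet-process prior unless the data insist
  otherwise.
- Greedy stage-1/stage-2 clustering is order-dependent only through
  deterministic tie-breaking; different tie-break conventions can give
  different (equally valid) outputs on heavily tied matrices.
- Replicated designs must be reduced to one profile per entity before
  loading; no replicate-aware likelihood is provided.
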