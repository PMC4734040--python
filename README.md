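# plsmix

Model-based clustering of biological time series — transcript, protein or
metabolite profiles measured over a (possibly unequally sampled) time
course — with an **infinite mixture of piecewise linear sequences**,
followed by a deterministic two-stage clustering of the posterior
co-clustering matrix and optional GO-term enrichment of the resulting,
possibly overlapping, clusters.

It is aimed at analysts of dynamic experiments (perturbation responses,
developmental courses, circadian sampling) who want clusters that respect
the *shape* of a trajectory over experimental phases rather than treating
time points as exchangeable features, and who do not want to fix the
number of clusters in advance.

## The model

Time points are grouped into S contiguous *segments*; within each segment
a trajectory is linear, and discontinuous jumps are allowed between
segments. A piecewise linear sequence (PLS) is parameterized by

```
mu = (init, slope_1, jump_2, slope_2, ..., jump_S, slope_S),   L = 2S
```

and a fixed design matrix C (M × L) maps `mu` to the M per-time-point
means, so slopes multiply *real* time offsets and unequal sampling is
handled naturally. Profiles are generated by a Pitman-Yor mixture:

```
z_1:N | alpha, d   ~ CRP(alpha, d)                 (partition prior)
mu_k               ~ N(0, Sigma_mu)                (flat-ish PLS prior)
lambda_k | a, b    ~ Gamma(a, b)                   (component precision)
x_i | z_i = k      ~ N(C mu_k, lambda_k^{-1} I)
```

A collapsed MCMC sampler (mu_k integrated out analytically;
Metropolis-Hastings for lambda_k and the hyper-parameters; collapsed
Gibbs with auxiliary-variable proposals for z_i) yields the posterior
probability that any two entities share a component. The two-stage
clustering then (1) merges singletons under complete linkage while the
best link is at least the merge threshold m, and (2) extends clusters
with outside entities while the worst member similarity is at least the
extension threshold e — the extension step is what lets one gene belong
to several clusters. Enrichment p-values are upper-tail hypergeometric,
Bonferroni- or Benjamini-Hochberg-corrected.

## Worked example

Simulate a 3-cluster dataset from the generative model, then run the
phases (CONF → INF → CLUS):

```
$ plsmix simulate --clusters 3 --sizes 20,20,20 --noise-sd 0.2 --seed 7 \
      --out synth.tsv --truth truth.tsv
60 entities x 8 time points -> synth.tsv

$ plsmix conf --input synth.tsv --manual "1-4;5-8" --out model.json
segments: 1-4;5-8  (L=4) -> model.json

$ plsmix inf --input synth.tsv --model model.json --chains 2 \
      --iterations 2000 --skip 500 --seed 1 --out sim.tsv --trace trace.tsv
similarity matrix (60x60) -> sim.tsv
MH acceptance rates: {'lambda': 0.137, 'a': 0.103, 'b': 0.100, 'alpha': 0.892, 'd': 0.948}

$ plsmix clus --sim sim.tsv --merge 0.5 --extension 0.5 \
      --input synth.tsv --out clusters.tsv --metrics metrics.tsv
3 clusters (0 singletons, largest 20) -> clusters.tsv
```

The three recovered clusters are exactly the three planted groups
(`C1 = g0001..g0020`, and so on), and `metrics.tsv` reports a
Davies-Bouldin index of 0.0057 with mean intra/inter-cluster profile
distances of 0.72 / 241.0 — tight, well-separated clusters, as planted.
With real data you would pick the segmentation semi-automatically
(`plsmix conf --input X.tsv --sweep` lists the segmentation at every
candidate threshold) and add `plsmix eval --clusters clusters.tsv
--input X.tsv --obo go.obo --gaf annotations.gaf` for GO enrichment, or
run everything at once with `plsmix run`.

Library use mirrors the CLI: `generate_impls_dataset`, `run_chains`,
`two_stage_cluster`, `evaluate_clusters` et al. are importable from
`plsmix`.

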