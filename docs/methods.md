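# Methods

## The model

A chromosome painting expresses each recipient haplotype as a mosaic of
segments copied from a panel of donor haplotypes grouped into `D` donor
clusters. Summing segment lengths per donor cluster gives the recipient's
*copying vector* `l = (l_1, …, l_D)` with total `C` (the painted genome
length in cM, both haploid genomes). Homogeneous reference clusters —
*surrogates* for the unknown admixing source populations — have profiles
`f^s`, the unweighted mean of their members' normalised copying vectors.

The mixture model is

    l | β  ~  Multinomial(C; Σ_s β_s f^s_1, …, Σ_s β_s f^s_D)
    β | λ  ~  Dirichlet(λ_1, …, λ_S)
    λ_s    ~  Uniform(0, 10)

The simplex weights `β` are the recipient's ancestry proportions over the
`S` surrogates. Learning per-surrogate concentrations `λ` lets the prior
adapt: when few surrogates contribute, small `λ_s` values concentrate mass
near the simplex boundary and suppress spurious weights.

### Continuous lengths as pseudo-counts

Chunk lengths are continuous cM, not counts, so the multinomial pmf is
evaluated through its log-gamma generalisation on pseudo-counts
`l̃ = f · T`, where `f` is the normalised copying vector and `T` the
`effective_total` parameter. `T` controls posterior concentration: larger
`T` treats the copying vector as more informative. The default
(`"use-C"`) takes the recipient's rounded total `C`. For integer
pseudo-counts the log-likelihood equals the exact multinomial log-pmf
(tested against the factorial formula).

Mixture probabilities are floored at 1e-300 before logs, so a donor
cluster the recipient copies from but no surrogate covers produces a very
large finite penalty rather than `-inf`.

### The sampler

Each MCMC iteration:

1. **β update (Metropolis–Hastings).** Draw one step size
   `Y ~ Uniform(0, 0.1)`; add `Y/5` to five components sampled with
   replacement, subtract `Y/5` from five components sampled with
   replacement, clamping every touched entry into `[1e-7, 1 − 1e-7]`;
   renormalise; accept with probability
   `min(1, posterior(β′)/posterior(β))`. The single `Y` is reused for all
   ten sub-moves. The clamp-then-renormalise proposal is treated as
   symmetric (no Hastings correction); the quadrature comparisons below
   bound the bias this induces (observed ≈ 0.002 on the S=2 check, well
   inside the 0.02 acceptance band).
2. **λ update.** For each `s` in turn, propose
   `λ′_s ~ Normal(λ_s, 0.2)`; reject automatically outside `[0, 10]`,
   otherwise accept with probability `min(1, Dir(β|λ′)/Dir(β|λ))`. The
   ratio is computed incrementally in scalar log-gamma terms (only the
   `s`-th component changes), which is algebraically identical to the full
   density ratio and much cheaper.

Chains start from `β(0) ~ Dirichlet(0.5, …, 0.5)` and `λ(0) = 0.5`.
Production settings run 200,000 iterations thinned every 1,000 and
combine 50 independent runs; tests and simulations use smaller values
(noted below) because the posterior for the problem sizes involved mixes
within a few thousand iterations.

### Combining runs

Each run contributes its maximum-posterior thinned draw. The final
estimate is the softmax-weighted average of these draws, weights
`exp(logpost_i − max_j logpost_j)` normalised to 1. Unnormalised
posterior densities across runs differ by large log factors, so softmax of
log posteriors is the numerically meaningful reading of
"weighted by posterior probability"; in practice the best run dominates
whenever chains disagree.

Determinism: run `i` uses generator seed `base_seed + i`; identical
configurations give bit-identical estimates.

## NNLS baseline

`nnls_mixture` solves `min ‖F w − f‖², w ≥ 0` (active-set NNLS) and
rescales `w` to sum to one afterwards; the residual is reported before
rescaling. The sum-to-one condition is deliberately not a solver
constraint — it mirrors the mixture-regression convention this baseline
reproduces. On noiseless full-rank mixtures it is exact to machine
precision; on sampled vectors it is the comparator for the Bayesian
estimates (agreement within 0.03 per component on noiseless recipients is
a tested invariant).

## Synthetic panels

`make_profiles` draws each surrogate profile as
`(1 − sep) · Dirichlet(1,…,1) + sep · e_i` with a distinct basis column
per surrogate, so `sep` (separation, in [0,1]) directly controls pairwise
total-variation distance. Recipients are `Multinomial(T, Σ_s β_s f^s)`
draws — exactly the inference likelihood, so parameter recovery is tested
without model misspecification. An optional Dirichlet-multinomial
over-dispersion knob perturbs the cell probabilities first, for robustness
stress-tests. `make_drifted_surrogate` moves profile mass onto a private
self-copy column, emulating a strongly drifted reference cluster; the
tested property is that such a surrogate receives negligible weight
(< 0.02) for recipients lacking that signature.

What the generator does *not* emulate: linkage between donor segments,
per-chromosome painting noise, uncertainty in the surrogate profiles
themselves (profiles are treated as known), or relatedness between
surrogates beyond what the separation mixing induces. Passing recovery
tests therefore show correctness of the estimator under its own model,
not robustness to painting artefacts in real panels.

### Problem sizes used in tests and the acceptance script

- Posterior-vs-quadrature: S=2 (2,001-point grid) and S=3 (0.005-step
  simplex grid), `T` = 100–200, `λ` fixed at 1, chains of 60,000–100,000
  iterations; agreement required within 0.02 on means, 20% on variances.
- Parameter recovery: S=5, D=10, separation 0.9, `T` = 20,000, 20
  replicate recipients, chains of 20,000 iterations × 4 runs. Observed
  max-abs error ≈ 0.008.
- The λ update is validated on a fixed β against a 400×400 quadrature of
  the Dirichlet density over [0,10]²; the sd-0.2 random walk is heavily
  autocorrelated, so the comparison tolerance (0.5 on a posterior mean of
  ≈ 4–7 with posterior sd ≈ 2.5) reflects Monte-Carlo error, not model
  disagreement.

## Admixture-date post-processing

Event tables from haplotype-decay dating carry one of three categories:
single date/two sources, single date/multiway, multiple dates. Complex
categories are simplified to two two-source single-date events each; when
per-pulse details are unavailable the record is emitted twice as the pair
it stands for. Filters: events dated exactly 1 generation are dropped (a
known no-admixture artefact, and over-represented), events whose source
contributes ≤ 5% ancestry, and events ≥ 30 generations (pre-colonial).
Calendar conversion uses `y = 1990 − 28·(g + 1)` — cohort mean birth year
1990, generation time 28 years — so g=0 maps to 1962.

Date-distribution comparisons use the one-sided Wilcoxon rank-sum test
with "more recent" encoded as *numerically smaller* generation dates:
exact enumeration when `nA + nB ≤ 12` with no ties, tie-corrected normal
approximation otherwise. An optional one-event-per-individual restriction
keeps the largest-source-fraction event as the "stronger signal".

## Ancestry-conditioned allele-frequency tests

Group membership: individuals with > 10% genome-wide ancestry of the
target Native component, < 1% combined other Native, < 1% East Asian.
At each SNP, only alleles on haplotypes with Native local ancestry enter
the frequency (numerator and denominator); SNPs with no qualifying
haplotypes are flagged undefined rather than zero.

Per-SNP differentiation uses a Welch unequal-variance t-test computed from
`(frequency, n)` summaries with the `n/(n−1)` sample-variance factor, so
it is algebraically identical to running `t`-test code on the raw 0/1
allele vectors (tested against that oracle), with Welch–Satterthwaite
degrees of freedom. Two monomorphic groups at the same allele give
`t = 0, p = 1`; at opposite alleles the result is flagged degenerate
(`p → 0`). FDR control is Benjamini–Hochberg at 0.05.

The joint test draws, for each index SNP, candidates matched on both
groups' haplotype counts (within 20) and on minor-allele frequency
(within 1%) in group A (set I) or group B (set II); index SNPs are
excluded from pools. The statistic is the mean −log p over the set;
10,000 random sets give an empirical p of `(k + 1)/(n + 1)` (the add-one
Monte-Carlo correction avoids zero p-values). The default tail counts
random sets *at least as* differentiated as the observed set (`tail="ge"`),
which is the internally consistent reading of "more differentiated than
usual"; `tail="le"` is available because the procedure has also been
described with the opposite inequality. The empirical p depends on the
per-SNP p-values only through their ranks, so it is invariant to monotone
rescaling of the statistic.

## Known limitations

- The sampler's proposal is treated as symmetric although clamping and
  renormalisation make it only approximately so; the induced bias is
  bounded empirically, not analytically.
- `effective_total` stands in for an unstated discretisation of cM
  lengths into counts; conclusions about posterior width depend on it.
- Surrogate profiles are plain member means; no outlier trimming.
- Recipients that are themselves surrogate members would need their zero
  self-copying column handled upstream; profiles are not re-weighted for
  it here.
- Split weights between (near-)identical surrogates are unidentifiable;
  only their sum is meaningful (tested).
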