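# Methods

## Model

For one gene with `n` reference samples and `p` cis-SNPs, both expression
`E` and the dosage columns of `X` standardized to mean 0 and unit sample
variance (divisor `n - 1`, the single convention used throughout), the
imputation model is

```
E = X b~ + X xi + e,          e  ~ N(0, s_e^2 I_n)
b~_k | z_k = j                ~ N(0, s_e^2 s_j^2),   k = 1..p
xi                            ~ N(0, s_e^2 s_0^2 I_p / p)
s_e^2 ~ IG(a_e, b_e),  s_0^2 ~ IG(a, b),  s_j^2 ~ IG(a, b)
```

The dense component `X xi` is the familiar polygenic random effect: its
marginal covariance is `s_e^2 s_0^2 K` with `K = X X' / p` the genetic
relatedness matrix.  The sparse-ish component `b~` carries the
annotation structure through the latent clustering `z`, with the PPMx
prior

```
P(Z | W) ∝ prod_j g(W*_j) C(S_j),        C(S) = (|S| - 1)!
g(W*_j)  = prod_l prod_{t in S_j} phi(W_tl | mu_hat_jl, max(s2_hat_jl, floor_l))
```

`mu_hat_jl` and `s2_hat_jl` are the cluster's own sample mean and sample
variance of annotation `l` (a "double dipping" plug-in similarity).  Two
limits anchor intuition: with the similarity switched off the prior is
exactly the Ewens partition weight of a unit-mass Dirichlet process, i.e.
the annotation-agnostic special case; with tight, well-separated
annotation groups the prior concentrates on the partition matching those
groups (verified by exhaustive enumeration over all 203 partitions of six
SNPs in the tests).

### Similarity details

* **Variance convention.** The plug-in variance uses divisor `|S| - 1`,
  matching the package-wide sample-variance convention.
* **Variance floor.** `floor_l = variance_floor_frac × Var(W_l)` (global
  sample variance; default fraction 0.01, absolute floor 1e-12).  Without
  it a cluster with identical scores has infinite plug-in density.  Note
  the floor sets the scale against which "similar" is judged: a cluster is
  rewarded when its within-cluster spread falls at or below the floor.
* **Singletons.** A singleton's sample variance is undefined; it
  contributes the density at its own mean with the floor variance,
  `-(1/2) log(2 pi floor_l)` per annotation, keeping the prior finite and
  continuous in cluster size.
* **Dirichlet-process mass.** Fixed at 1 (the cohesion carries no mass
  factor).

## Gibbs sampler

All randomness flows through one `numpy` Generator seeded from the config,
so a fixed seed and input give bit-identical results.  One sweep:

1. **Cluster labels.** Each `z_k` in turn is resampled from the
   conditional over occupied clusters plus one auxiliary new cluster whose
   variance is a fresh `IG(a, b)` draw (the standard auxiliary-variable
   device for non-conjugate DP-style priors).  The weight of cluster `j`
   multiplies the partition-prior ratio (cohesion ratio `|S_j|`, similarity
   ratio from the cluster's sufficient statistics) by
   `N(b~_k | 0, s_e^2 s_j^2)`.  Per-cluster sums and sums of squares of the
   annotation scores make each evaluation O(m).
2. **`b~`,** coordinate-wise from its exact Gaussian conditional with a
   maintained residual vector (avoids p×p solves; exactness preserved).
3. **`xi`,** block-wise from its Gaussian conditional, solved in the
   eigenbasis of `X'X` computed once per fit.
4. **`s_j^2 | b~, z ~ IG(a + |S_j|/2, b + sum_{k in S_j} b~_k^2 / (2 s_e^2))`.**
5. **`s_0^2 ~ IG(a + p/2, b + p xi'xi / (2 s_e^2))`.**
6. **`s_e^2 ~ IG(a_e + (n + 2p)/2, b_e + [ ||E - X b~ - X xi||^2 +
   sum_k b~_k^2 / s_{z_k}^2 + p xi'xi / s_0^2 ] / 2)`** — the shape counts
   the `n` residual terms plus the `p` `b~` and `p` `xi` terms whose prior
   variances are scaled by `s_e^2`.

Labels are compacted after every sweep (empty clusters removed, clusters
renumbered by first occurrence) for reproducibility.  The correctness
anchor is the ridge limit: with the partition frozen at one cluster and the
variances fixed, the posterior mean of `b~ + xi` must equal the closed-form
ridge estimator `(X'X + I/c)^{-1} X'E` with `c = s_1^2 + s_0^2/p`; the
tests verify agreement to < 0.02 at n=200, p=20 over 5 chains.

**Defaults.** `a_e = b_e = a = b = 0.01` (weakly informative),
`n_iter = 2000`, `n_burnin = 1000`, `thin = 2`.  Desk-scale genes
(p ≤ 1000) mix adequately under this schedule; all values are exposed in
`MaatConfig`.

### Importance scores and sparsification

Each SNP inherits its cluster's effect-size scale `s_e^2 s_{z_k}^2`.  The
per-SNP importance is the **geometric** posterior mean of that quantity
over retained draws, `exp(mean log s_e^2 s_{z_k}^2)`.  The geometric rather
than arithmetic mean is deliberate: the inverse-gamma full conditional of a
singleton cluster has shape `a + 1/2 < 1` and hence infinite mean, so an
arithmetic average over draws is dominated by rare enormous excursions of
transient singletons, destroying the ranking; the geometric mean is a
finite, scale-equivariant location summary of the same draw sequence and
coincides with the draw itself when the chain is degenerate.

Sparsification at level `q` keeps the `ceil(q p)` highest-importance SNPs
with their unmodified posterior-mean weights (no refit); ties break by
larger absolute weight, then lower SNP index.  Default levels: 5, 10, 20,
30 %.

## Association stage

* **LD.** `V = X'X/(n_ref - 1)` from a standardized panel, shrunk as
  `V <- (1 - lambda) V + lambda I` with `lambda = 0.1` by default — the
  shrinkage guards the burden denominator against near-singular LD for
  long genes when the panel is external.
* **Burden test.** `Z = z'w / sqrt(w'Vw)`, two-sided normal p-value;
  all-zero weights or a denominator at numerical zero are flagged
  degenerate rather than tested.
* **ACAT.** Component p-values are clamped to `[1e-15, 1 - 1e-15]` before
  the tangent transform.  ACAT is a tail approximation: under dependent
  components its combined p-value is calibrated at the small significance
  levels where decisions are made but visibly non-uniform mid-range, so
  calibration checks target rejection rates at working levels rather than
  global uniformity.
* **Harmonization.** External statistics are matched to model SNPs by
  identifier; a differing effect allele flips the sign; strand-ambiguous
  (A/T, C/G) pairs are matched by letter with a warning, never
  strand-flipped; SNPs missing from the summary data are dropped and
  reported.
* **Multiple testing.** Bonferroni at `alpha / n_genes` (default
  `alpha = 0.05`).

## Annotation assignment

With `V = U L U'`, vectors are rotated by `L^(1/2) U'`; eigenvalues below
`1e-8 ×` the largest are dropped (rank reduction) rather than floored,
because `L^(1/2)` on near-null LD directions only amplifies noise.
Annotation columns are centered before rotation (the cosine is
location-sensitive; configurable).  The phenotype-effect proxy `alpha` is
the harmonized marginal GWAS Z-score vector — the cosine is scale-free, so
the unit is immaterial.  Scores `|cos(W_l_rot, b_rot) + cos(W_l_rot,
a_rot)|` lie in [0, 2]; ties go to the lowest index with a flag.  No
significance test accompanies the assignment; treat per-gene assignments as
descriptive and aggregate over genes.

## Synthetic data

The generators emulate the reference study conditions: 500 training / 125
testing samples (4:1), 1000 cis-SNPs (scaled down in the test harnesses),
MAF uniform on [0.05, 0.5], five annotations of which two are informative,
expression heritability `h_e2 ∈ {0.1, 0.2, 0.5}`, phenotype heritability
`h_p2 ∈ {0.1, 0.25, 0.5}`, causal proportion `p_cs ∈ {0.01, 0.05, 0.1,
0.2}`, 50 expression replicates with 100 phenotype replicates per power
cell and 100,000 per type-I cell at nominal level 0.05.

* **Genotypes** are a Gaussian-copula stand-in for real cohort data:
  latent block-AR(1) vectors (`rho = 0.7`, block size 50 by default),
  dichotomized twice per individual at the MAF quantile and summed, giving
  Hardy-Weinberg dosages with realistic local LD.  Blocks whose realized
  MAF leaves [0.04, 0.51] are redrawn.  Dichotomization attenuates the
  latent correlation (phi < tetrachoric), most strongly for mismatched
  MAF pairs — the realized adjacent-dosage correlation at `rho = 0.9` has
  median ≈ 0.6.
* **Annotations**: non-informative columns are N(0,1) everywhere;
  informative columns shift the causal SNPs' mean by 2 (configurable).
  The separation value and the 4:1 causal-group variance ratio are
  package choices exposed as config knobs.
* **Effects/expression**: causal effects from two mean-zero normals
  (variance ratio 4 across a random two-way split of the causal set),
  rescaled so the *sample* heritability of `X beta` is exactly the target;
  `e ~ N(0, 1 - h_e2)`.
* **Phenotype**: `Y = sqrt(h_p2) E_std + e1`, `e1 ~ N(0, 1 - h_p2)`; the
  null phenotype is i.i.d. N(0,1), independent of genotypes.

Genotypes, the causal set and the annotation matrix are fixed per
experiment (mirroring a fixed real reference gene); effect sizes,
expression and phenotypes are redrawn per replicate.  Per-replicate
generators are forked deterministically as `default_rng([seed, stream,
replicate])`.

Inside the harnesses the summary statistics are marginal regression
Z-scores of the phenotype on each standardized test-split SNP,
`z_k = sqrt(n-1) corr(x_k, y)`, and the LD matrix is estimated from the
same test split.  Because panel and GWAS sample coincide, `w'z /
sqrt(w'Vw)` is exactly pivotal under the null given the genotypes, so the
harness default is no LD shrinkage (`ld_regularization = 0`); the external
`lambda = 0.1` default still applies to the file-based association path.

**What the generator does not emulate:** real allele-frequency spectra and
long-range LD, population structure and relatedness, annotation score
distributions (real integrative scores are heavy-tailed and correlated),
expression measurement artifacts and confounders, and binary phenotypes
with realistic prevalence.  Passing simulations therefore demonstrate the
machinery's statistical behavior under the stated generative conditions,
not performance on any particular cohort.

## Numerical choices

* Missing genotype entries are filled with the column mean at read time;
  monomorphic columns are rejected with the SNP named.
* Gamma draws underlying inverse-gamma sampling are floored at 1e-300 to
  avoid division by zero in the extreme tail.
* The sampler recomputes the full residual after the `xi` update each
  sweep, preventing drift from the incremental coordinate updates.
* A non-finite log posterior aborts the fit with the offending state
  summarized.
* Cosines against near-zero-norm (≤ 1e-12) rotated vectors are defined as
  0; degenerate effect vectors raise with the vector named.

## Scales used in the shipped checks

The package's own test suite and acceptance script run everything at desk
scale, chosen to exercise the full pipeline while keeping single-CPU runs
short: the null-calibration experiment uses one fit at n=500 training
samples and p=300 SNPs with 10,000 null phenotypes; recovery checks use
p = 20–100 with 10–150 seeds and shortened chains (200–1500 iterations).
The defaults in `SimConfig` remain the full study conditions.

## Known limitations

* The exact form of the similarity function, the supplemental sampler
  variant and the original importance-score formula are not public; the
  plug-in similarity, the auxiliary-variable sampler and the geometric-mean
  score above are this package's own constructions consistent with the
  stated hierarchy.
* Under sign-symmetric causal effects the annotation-assignment signal is
  second-order (informative columns align with effect vectors only through
  energy concentration on the causal set), so per-gene assignments are
  noisy; the simulation checks need ≈150 replicates for stable
  comparisons.
* No refit after sparsification; retained weights keep their full-model
  posterior means.
* Strand ambiguity is not resolved; A/T and C/G variants are matched by
  identifier and allele letter only.
* Cross-tissue joint modeling, colocalization and fine-mapping are out of
  scope.
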