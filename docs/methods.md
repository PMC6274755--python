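# Methods

## Model

`anchornet` scores putative causal regulations A→B between a transcription
factor (TF) A and candidate target genes B, using the activity of an
enhancer E in A's regulatory neighbourhood as a causal anchor. All
variables are first transformed to standard normal by rank; each variable
is then modelled as Gaussian with mean linear in its regulators, so every
hypothesis about the trio is a Gaussian graphical model and the maximized
log-likelihoods are functions of the three pairwise sample correlations
ρ̂ = (1/n)Σ xᵢyᵢ (after the exact re-standardization, the 1/n and 1/(n−1)
correlation conventions give identical LLRs; we use 1/n throughout).

Five nested null/alternative pairs are tested:

| test | null | alternative | null of LLR/n |
|------|------|-------------|---------------|
| 1 primary linkage | E, A independent | E→A | D(1, n−2) |
| 2 secondary linkage | E, B independent | E→B | D(1, n−2) |
| 3 conditional independence | E→A→B (chain) | saturated | D(1, n−3) |
| 4 relevance | E→A, B isolated | saturated | D(2, n−3) |
| 5 controlled | B←E→A | saturated | D(1, n−3) |

D(k₁,k₂) has density p(z) = 2/B(k₁/2,k₂/2) · (1−e^{−2z})^{k₁/2−1} e^{−k₂z}
for z > 0 and 0 otherwise; equivalently x = 1 − e^{−2z} ~ Beta(k₁/2, k₂/2).
p-values are computed as the exact regularized-incomplete-Beta upper tail
of that transform, which the test suite verifies against adaptive
quadrature of the density itself (≤ 1e−8).

### Numerical form of the LLRs

The textbook expressions involve the determinant of the 3×3 correlation
matrix, det = (1−ρ̂²_EA)(1−ρ̂²_EB) − (ρ̂_AB − ρ̂_EA ρ̂_EB)², whose direct
evaluation cancels catastrophically when two variables are nearly
collinear (duplicate features, or coinciding rank patterns at small n).
Each LLR is therefore evaluated as −(n/2)·log1p(−q) with q an explicit
non-negative nesting ratio, using the exact factorizations

* test 3: (1−ρ̂²_EA)(1−ρ̂²_AB) − det = (ρ̂_EA t − ρ̂_EB(1−ρ̂²_EA))²,
* test 4: 1 − det/(1−ρ̂²_EA) = ρ̂²_EB + t²/(1−ρ̂²_EA),
* test 5: (1−ρ̂²_EA)(1−ρ̂²_EB) − det = t²,

where t = ρ̂_AB − ρ̂_EA ρ̂_EB. This makes non-negativity (nested
hypotheses) exact in floating point, and q ≥ 1 cleanly identifies singular
configurations. Correlations within 1e−12 of ±1 are clamped to
±(1 − 1e−12) before use, since real CAGE tables contain duplicated
features.

### Rank transform

Ranks (average rank for ties) are mapped to normal quantiles at
(r − 0.5)/n and then exactly re-centred/re-scaled to mean 0, variance 1
(1/n convention). The half-offset convention is symmetric and avoids
infinite quantiles; the exact re-standardization makes self-correlation
exactly 1 and every LLR a pure function of ranks, hence bit-invariant
under strictly increasing transforms of any input. Minimum sample size is
n = 5, below which the null family for tests 3–5 (k₂ = n−3) degenerates.

### Binary anchors

An enhancer used in binary mode is reduced to its zero/non-zero indicator,
standardized to mean 0, variance 1, and fed through the same continuous
formulas. For two categories this is algebraically the categorical
group-mean (one-way ANOVA) model — the linkage LLR equals
−(n/2) ln(RSS_group/RSS_total) — with the same D(1, n−2) null, so one code
path serves both encodings (property-tested against an explicit ANOVA fit
to 1e−10). Anchors that are all-zero or all-nonzero have no binary
encoding and are dropped from the candidate list.

### Posteriors

Within one (E, A) pair, each test's p-values over all candidate targets
form a mixture f(p) = π₀·1 + (1−π₀)f₁(p). The posterior probability of
the alternative at p is 1 − π₀/f̂(p), clipped to [0,1], with
π₀ = min(1, 2·mean(p > 0.5)) and f̂ the Grenander estimator (slopes of the
least concave majorant of the p-value ECDF), which is non-increasing, so
posteriors are monotone non-increasing in p. Pooling is per test within a
TF, not across TFs, matching the per-anchor "all candidate targets"
framing of the procedure. With fewer than 50 candidates the Grenander
estimate is unstable and the conservative fallback 1 − p is used (with a
warning). Test 3 is special: its *null* (conditional independence) is the
supported causal model, so its contribution to the traditional score uses
the posterior of the null, i.e. the complement.

The combined causality score is P = ½(P₂P₅ + P₄); the traditional
conditional-independence combination P₂·P₃ is provided as a baseline. The
empirical-Bayes conversion is a deliberate, self-contained local-FDR
scheme behind a single interface (`posteriors_from_pvalues`), so a
different converter can be swapped in without touching the tests' LLR/
p-value layer.

## Pipeline conventions

* Genes are kept when TPM ≥ 1 in at least one sample, then transformed as
  log₂(TPM + 1). The base-2/pseudocount-1 choice is the package's
  convention (configurable); the downstream rank transform makes it
  irrelevant to the statistics, but the filtered matrix is also what users
  export. The filter's *selection* rule is idempotent; the log transform
  is applied once, to raw TPM.
* Enhancers are kept when non-zero in strictly more than n/3 samples, and
  are never log-transformed (zeros define the binary encoding).
* "Zero read count" is interpreted as TPM == 0 exactly; raw tag counts are
  not part of the input format.
* Each TF is represented by its promoter with the highest median
  expression (ties: lexicographically smallest ID).
* Candidate anchors are enhancers whose **midpoint** lies within 50 kb
  (inclusive) of the TF's TSS, midpoint-to-point being symmetric for
  bidirectional enhancers; coordinates are BED-style 0-based half-open,
  TSS are 1-bp features, strand is ignored for distances.
* Ground truth: ChIP targets are genes with a peak within 1 kb (inclusive,
  gap 0 when overlapping) of their TSS; knock-out targets are genes with
  differential-expression q strictly < 0.05.
* A TF enters inference only if its best primary-linkage p-value is ≤ 0.05
  (configurable `primary_alpha`); the anchor must be significantly linked
  to the TF for the trio logic to mean anything.
* Adaptive selection tries every candidate enhancer in both encodings and
  takes the minimal primary p-value; exact ties prefer the continuous
  encoding (more information retained). The adaptive fit is, by
  construction and by test, bit-identical to running the selected
  single-mode method directly. Whether to force both modes onto one
  fixed enhancer instead is exposed through `mode=` on the model.
* Enrichment universes are the genes actually scored for a TF (post
  filtering, TF excluded), not the whole genome — using the genome would
  inflate significance for no gain. Score thresholding at 0.8 is strict
  (score > threshold). PR curves use the interpolation-free step integral
  and report prevalence as the random-classifier baseline.

## Multi-enhancer consensus utilities

Two integrators over a TF's enhancer set: the per-sample **median**
expression ("meta-enhancer"), usable as an anchor in either mode; and the
first principal component of the enhancers × genes binary prediction
matrix, sign-fixed to correlate non-negatively with the per-gene
prediction means (eigenvector sign is otherwise arbitrary and tests need
determinism). When all enhancer rows agree, the centered matrix is zero
and the consensus is defined as the common centered pattern. Target-set
similarity uses Jaccard with average-linkage hierarchical clustering and
a deterministic leaf order.

## Synthetic data generator

The generator emulates the *structure* of CAGE data — zero-inflated eRNA
vectors, log-scale positive gene expression, trios with confounding and
pleiotropy — not FANTOM5's marginal distributions. Per TF: a causal
enhancer E (binary truth: Bernoulli on/off with the off-probability equal
to `enhancer_zero_inflation`, positive values log-normal noise; continuous
truth: log-normal left-censored at the `zero_inflation` quantile, the
uncensored latent driving the TF), a per-TF Gaussian confounder C, then
A = effect_ea·E + conf·C + ε and for true targets
B = effect_ab·A + conf·C + ε with unit Gaussian ε. A fraction
`pleiotropy_fraction` of non-targets receives a direct E effect of size
effect_ea·effect_ab (matching the chain's total E→B path) — the foils the
controlled test exists to reject. Latent values are exponentiated to a
TPM-like scale (log-mean 2, log-sd 0.5 for genes; 1 and 0.5 for
enhancers; clipped at |log| ≤ 50 so extreme effect sizes cannot overflow).
Decoy enhancers (default 2 per TF) are independent noise with the same
marginal structure, exercising the adaptive selector across enhancers.

The benchmark preset `confounded-network` uses 50 samples (a typical
per-cell-type CAGE series), 10 TFs × 100 disjoint true targets among 2000
genes, effect_ea 0.8, effect_ab 0.6, confounder 0.4, pleiotropy 0.1,
zero-inflation 0.3, mixed anchor-mode truth. `binary-anchors` /
`continuous-anchors` fix the mode truth to probe adaptive selection, and
`null` switches off effect, shared confounding and pleiotropy together so
that true targets are genuinely indistinguishable from the rest (leaving
the confounder on would itself be a real A–B association). Equal seeds
give bit-identical datasets.

What passing on these data does **not** show: robustness to unequal
sample relatedness (replicates, time series), to eRNA measurement noise
at very low expression, or to FANTOM5-scale feature counts; the generator
draws independent samples and moderate dimensions by design.

## Problem sizes

The default test suite and the acceptance script use: 200 trios for the
maximum-likelihood oracle comparison, 10⁴ replicates at n = 30 for null
calibration, 20 seeds of the benchmark scenario for enrichment/AUPR, and
5 seeds per mode-truth scenario for adaptive selection — sizes at which
every check is stable across seeds while the whole suite runs in well
under a minute per section.

## Known limitations

* The local-FDR posterior is a pragmatic substitute for fitting the exact
  null/alternative density mixture per test; it is conservative under
  sparse alternatives and undefined below 50 candidates (fallback 1 − p).
* π₀ = min(1, 2·mean(p > 0.5)) assumes alternatives concentrate below
  p = 0.5; heavy pleiotropy can violate this mildly for test 3.
* Anchors with more than two discrete levels (eQTL genotypes with three
  genotype classes) are out of scope; binary/continuous enhancers only.
* Per-TF rankings are not assembled into a global directed network; cycle
  resolution is left to downstream tooling.
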