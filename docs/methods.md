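# Methods

This note records the statistical model behind each stage of the pipeline,
the defaults and why they were chosen, the numerical decisions that a user
re-deriving results would need to know, and what the synthetic data do and
do not emulate.

## Drift model and kinship

All scans rest on the Gaussian approximation to genetic drift: for a SNP
that was polymorphic at frequency `p0` in the ancestral population, the
frequency vector across present-day populations is

    p ~ N(p0 · 1,  p0 (1 − p0) F)

with `F_ij` the drift shared by populations `i` and `j` on their
root-to-leaf paths. `F` is estimated in three steps: pairwise Reynolds
distances from allele frequencies, a neighbour-joining tree on those
distances, outgroup rooting, and path-sum extraction of `F` from the rooted
tree with the outgroup pruned (drift is measured from the ingroup
ancestor, which is what the test conditions on).

**Reynolds-to-drift scaling.** The pairwise Reynolds distance estimates the
coancestry of a population *pair* — under pure drift approximately half the
drift accumulated along the path separating the two populations (each
population contributes its own branch; the two-population FST of
populations that each drifted `f` is `f`, not `2f`). Branch lengths fitted
to raw Reynolds distances would therefore come out in half drift units and
`F` would be half its proper scale, doubling every FLK statistic.
`build_kinship` consequently doubles the distances before tree fitting
(`REYNOLDS_TO_DRIFT = 2`). With this scaling, the estimated `F` diagonal
recovers the generating drift within a few percent at 20,000 SNPs and the
FLK null calibration with estimated `F` matches the calibration with the
true `F` (both verified in the acceptance suite).

**Numerics.** Negative NJ branch lengths are clamped to zero with the
deficit shifted to the sibling, preserving path lengths where possible.
The root is placed at the midpoint of the outgroup's branch. `F` inversion
adds a `1e-8` ridge only if the condition number exceeds `1e12`. Local
trees re-fit branch lengths by non-negative least squares of leaf-to-leaf
path lengths against regional Reynolds distances (doubled as above) with
the topology fixed; the two edges meeting at the root are not separately
identifiable from leaf-to-leaf distances, so they are fitted as one
parameter and split in the genome-wide proportion. An elongated terminal
branch in the local tree relative to the genome tree marks the population a
sweep acted on.

## QC chain

Order: sample missingness → SNP filters (monomorphic, then missing-rate,
then Hardy–Weinberg) → relatedness. Each removed item carries the first
failing reason; the chain is idempotent (re-filtering a filtered table
removes nothing, which the tests assert).

The HWE test is the conditional exact test (probability-ordering, no mid-p
correction), computed by the outward recurrence from the modal heterozygote
count; a chi-squared variant is available. Exact-test p-values are
discrete, hence conservative rather than exactly uniform under the null —
the test suite checks validity (`P(p ≤ a) ≤ a`) rather than KS uniformity.
Multiple-testing control uses Storey q-values with the cubic-smoother π0
estimate (falling back to π0 = 1, i.e. Benjamini–Hochberg, below 100
tests, where the smoother is meaningless).

The genomic relationship matrix is VanRaden method 1 with missing calls
mean-imputed to `2p`. Off-diagonal coefficients are modelled per breed as
a two-component normal mixture fitted by EM (quantile-based initialisation,
seeded restarts); a pair is flagged related while the running mean of the
sorted posterior probabilities of belonging to the major (unrelated)
component stays below the FDR target. Two guards matter in practice:
(i) if a component collapses onto a point mass the fit is degenerate and a
fixed coefficient threshold (0.35) takes over with a warning; (ii) if the
non-major component's mean does not exceed the major mean by at least three
major-component standard deviations, the mixture is merely splitting the
unrelated bulk and nothing is flagged. Without the second guard, small
noisy panels (tens of samples at a few hundred SNPs) lose many unrelated
samples. Removal is greedy — the sample in the most flagged pairs first,
ties to the lexicographically smallest id — so output is deterministic.

LD decay uses the composite (genotype-correlation) r², requiring no
phasing, binned by pairwise distance (50 kb bins to 5 Mb by default) and
averaged over chromosomes.

## FLK

The ancestral frequency is the best linear unbiased estimate
`p̂0 = (1'F⁻¹p)/(1'F⁻¹1)`, clamped to [0, 1]. SNPs with estimated ancestral
minor allele frequency below 5% are removed (the model assumes ancestrally
polymorphic SNPs). The statistic is referred to chi-squared with `n − 1`
degrees of freedom, one lost to estimating `p̂0`. SNPs with any scanned
population undefined are dropped rather than imputed. Significance is
controlled at FDR 1% by default (Storey q-values); leave-one-population-out
re-scans are supported and equal a scan built from scratch on the reduced
panel.

## Haplotype-cluster model and hapFLK

Local haplotype structure is summarised by a hidden Markov chain over `K`
clusters: cluster `k` emits allele B at SNP `s` with probability
`theta[k, s]`; between consecutive SNPs the chain jumps with probability
`rho[s]` and on a jump re-draws the cluster from the local weights
`alpha[:, s]` (the simplest mosaic parameterisation; distance-dependent
jump rates are not implemented). Fitting is by EM — a haploid chain on
phased haplotypes, a diploid chain over ordered cluster pairs on unphased
genotypes (factorised transitions keep the E-step at `O(K²)`–`O(K³)` per
SNP) — with the observed-data log-likelihood asserted non-decreasing every
iteration. `theta` is floored at `1e-4`, `alpha` at `1e-6`, preventing
absorbing states. The haploid E-step and its M-step sufficient statistics
are fused into a compiled kernel; a pure-numpy reference implementation of
the same recursions is kept and the two are asserted equal in the tests.

EM is sensitive to initialisation. Each fit races several short runs — a
k-means partition of the sequences (which almost always identifies the
right basin) against random single-sequence anchors — and continues the
best short-run log-likelihood for the full iteration budget. Scans average
the statistic over several independent EM fits (5 by default).

hapFLK applies the FLK quadratic form at each SNP to the population ×
cluster frequency matrix, centered on the `F`-weighted ancestral cluster
frequencies, against the Kronecker covariance `F ⊗ (diag(q0) − q0 q0')`.
The cluster simplex makes the covariance singular, handled by a
Moore–Penrose pseudoinverse with a relative eigenvalue cutoff of `1e-2`.
The cutoff is not cosmetic: a cluster whose local ancestral frequency is
near zero has near-zero drift covariance but its estimated frequency still
carries finite-sample noise, so near-null directions explode when inverted
(observed null skew of 12 with a 99th percentile 40× the median at the
`1e-10` cutoff); dropping directions below 1% of the leading eigenvalue
removes exactly those clusters and leaves a well-behaved null. With
`K = 2` the pseudoinverse has a single non-null direction and hapFLK
reduces exactly to the biallelic FLK on cluster-1 frequencies (asserted to
`1e-8`).

Because the null distribution of hapFLK depends on the fitted cluster
model, p-values come from fitting a scaled chi-squared `c · χ²(d)` to the
genome-wide empirical distribution. The fit matches empirical quantiles to
scaled chi-squared quantiles over the 2nd–98th percentiles (top 2%
excluded so genuine selection signals do not inflate the null; for fixed
`d` the optimal `c` is linear least squares, `d` is a bounded 1-d search).
Quantile matching was chosen over body-weighted likelihood or moment fits
because it anchors the fit in the tail region where significance is
decided: on pure `2·χ²(6)` draws it recovers `(c, d)` within a few percent
with KS-uniform p-values, and on simulated neutral scans the recalibrated
`P(p < 0.05)` sits at 0.047–0.055 across seeds.

## Regions and genes

Significant SNPs within 1 Mbp on the same chromosome chain into one
selection signature; region boundaries are the span of the member SNPs,
not gap-extended (the convention used for all length statistics). Regions
below the gene-annotation threshold (10 SNPs for FLK scans, 5 for hapFLK)
are reported but flagged. Genes from GFF3 overlap a region by any base;
ranking uses the distance from the gene midpoint to the best (smallest-p)
SNP, ties to the smaller gene id, strand ignored. Region-set comparison
classifies regions by any-bp overlap and reports count and mean-length
summaries.

## Allelic heterogeneity

For a signature detected by FLK, the SNP set is: all SNPs with `p < 0.001`,
padded to the 10 smallest-p SNPs if fewer, capped at the 40 smallest-p
SNPs if more (all within the region span). Writing `F = U Λ U'`, each
SNP's loading vector

    w_s = Λ^(−1/2) U' (p_s − p̂0_s 1) / sqrt(p̂0_s (1 − p̂0_s))

satisfies `‖w_s‖² = FLK_s` exactly (a hard identity asserted at `1e-8`
throughout the tests). Eigenvalues of `F` below `1e-10` are dropped. The
SNP–SNP correlation matrix is the cosine similarity of loading rows —
correlation between FLK tests comes from shared population history as well
as linkage, and this construction captures both.

The configuration posterior treats the signed scores
`z_s = ±sqrt(FLK_s)` (sign from the projection of `w_s` on the first
principal component of the loading matrix, giving a consistent orientation
within the region) as `N(0, R + λ² R diag(c) R)` for a configuration `c` of
associated SNPs, with prior `γ^|c| (1 − γ)^(m−|c|)` truncated at 10
variants. Defaults `γ = 0.01` and `λ = 5.2` are reported in output
headers; both are exposed because no canonical values exist for this
repurposing. The Gaussian quadratic form and determinant are evaluated
through rank-`|c|` Woodbury identities (`R⁻¹R[:, c]` collapses to identity
columns), so each configuration costs `O(|c|³)`. All configurations are
enumerated when their count is at most 2×10⁶; otherwise a seeded
Metropolis chain (toggle and swap moves) explores the space and the
posterior is computed by exact re-weighting over every configuration
visited (a shotgun-stochastic-search estimator, which agrees with exact
enumeration to ~10⁻³ posterior-mean units where both run — far tighter
than raw MCMC visit frequencies). A region is called heterogeneous when
the posterior mean number of variants is ≥ 2 or at least two SNPs have
marginal inclusion probability above 0.5; both quantities are reported.

The per-SNP scores are unsigned magnitudes of a `(n−1)`-dimensional
deviation, so null SNPs carry `E[z²] = n − 1` rather than 1; with small,
tightly-selected SNP sets (the 10/40 rules on FDR-1% regions) this inflates
the posterior mean only when many marginal SNPs enter a region, and the
binary heterogeneity call is robust to it (measured discrimination rates
are ≥ 90%/≥ 80% for one- vs two-variant scenarios). Treating the full
vector-valued deviations would require replacing the CAVIAR likelihood
itself, which is out of scope.

## Synthetic data: what it emulates, what it does not

The generator draws `p0` per SNP and diffuses frequencies down a rooted
tree, either by truncated-normal steps with variance `p0 (1 − p0) Δf` per
branch (the scans' own model) or by Wright–Fisher binomial sampling over
`round(2 Ne Δf)` generations (for cross-validation; the two engines agree
on mean Reynolds distances within 15%). Scenario defaults:

- **Neutral calibration**: 8 populations, total tree drift 0.2 (Dirichlet
  partition over branches), `p0 ~ U(0.25, 0.75)`, frequencies scanned
  directly. The intermediate `p0` range reflects SNP-array ascertainment
  toward common variants and keeps boundary truncation negligible, which
  is what makes the chi-squared null exact enough to test the statistic's
  calibration rather than the generator's boundary artefacts.
- **Sweeps**: `p0 ~ U(0.1, 0.9)` (a broader, more realistic spectrum) with
  selected loci drawn among SNPs with `p0 ≤ 0.3` and driven to fixation in
  one population — the hard-sweep picture of a rare beneficial variant
  rising to fixation. 25 diploids per population, 5 kb marker spacing.
- **Heterogeneity**: one 40-SNP window; either one locus fixed in one
  population or two loci fixed in two different populations.
- **Mosaic haplotypes**: `K` binary founder haplotypes, founder weights
  drifted along the tree on the logit scale (simplex-safe without
  rejection), mosaic switching at 0.02 per interval, 1% allele flip noise
  (genotyping error / recent mutation). Parameter-recovery conditions use
  mild weight drift (scale 1.5 instead of 4.0) because a founder that
  drifts to a few percent frequency in every sampled population is
  unrecoverable from data by construction, and the recovery test is meant
  to measure the fitter, not the sampling design.
- **Related pairs**: duplicates (kinship 1/2) and half-kin by gene-dropping
  one shared gamete (kinship 1/4).

Selection is an instantaneous displacement of the final frequency, not a
trajectory with a selection coefficient: FLK and hapFLK respond to the
final frequency pattern, and displacement keeps the truth exact. The
generator has no recombination-graph coalescent, no mutation model, no
ascertainment simulation and no LD between the frequency-level SNPs
(haplotype mosaics carry LD; frequency-level datasets are exchangeable
across SNPs). Passing tests therefore demonstrate calibration and power
under the scans' own model assumptions plus binomial sampling noise — not
robustness to demographic misspecification (migration, admixture,
bottlenecks), which the population-structure literature handles by pruning
problem populations before scanning.

## Problem sizes

The test and acceptance runs use desk-scale versions of the study design:
20,000 SNPs for null calibration, 50 replicates of 2,000 SNPs for sweep
power, 20 replicates per heterogeneity scenario, 5,000 SNPs × 160
haplotypes at `K = 5` for the hapFLK null, and 200 haplotypes × 200 SNPs at
`K = 3` for cluster recovery. These sizes give the quoted tolerances
adequate sampling precision (e.g. the mean of 20,000 chi-squared(7) draws
has a standard error of 0.026 against a ±0.14 band) while the whole suite
runs in minutes on one CPU.
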