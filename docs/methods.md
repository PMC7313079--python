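# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of the package. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Genotype representation and filters

Genotypes are held as a samples × variants matrix of alt-allele dosages
(0/1/2, `nan` for missing) with 1-based VCF coordinates; block
intervals are closed `[start_bp, end_bp]`. Only biallelic SNPs are
read; multi-allelic and indel records are skipped (not split) because
splitting creates dosage ambiguity. Heterozygous calls are kept as
dosage 1 even though the species selfs — residual heterozygosity is
real in landraces. The marker filter retains variants with call rate
≥ 0.90 and MAF ≥ 0.03 (computed on non-missing alleles; ties at the
threshold retained). The filter is idempotent and errors if it would
empty the panel.

## LD statistics

r² is the squared Pearson correlation of dosage columns over
pairwise-complete samples (composite LD). In a panel with ~95% selfing
the dosage correlation is essentially the haplotype correlation, which
is why no phasing is attempted. Pairs with fewer than 20 complete
samples or a monomorphic column are dropped. Unlinked pairs are sampled
without replacement across chromosomes (default cap 100,000 pairs); the
critical r² is by default mean + z₀.₉₅·sd of the unlinked values
(a parametric-normal 95th percentile; an empirical quantile is
available).

LD decay is fit by a hand-written second-degree LOESS (tricube weights,
local quadratic, default span 0.3 evaluated at 200 grid points):
`statsmodels.lowess` is degree-1 only, and the decay estimate wants the
curvature near the crossing. The decay range is the smallest distance
at which the fitted curve first reaches the critical r², linearly
interpolated between grid points; if the curve never crosses, the range
is reported as undefined rather than extrapolated.

## Haploblocks (Gabriel CI method)

For each close marker pair (default search window 500 kb) two-locus
haplotype frequencies are estimated by EM over unphased genotypes
(initialized at linkage equilibrium; converged at relative
log-likelihood change < 1e-10 or 1000 iterations; only the
double-heterozygote cell is phase-ambiguous). The genotype likelihood
is then evaluated on a |D′| grid (step 0.001) with allele frequencies
fixed at their sample values, normalized, and the CI bounds are the
points where 5% of the mass accumulates from each end (Haploview's
convention; the interval is widened by at most one grid step to contain
the EM point estimate). Classification: strong LD if CI ⊆ [0.7, 1] with
upper ≥ 0.98; recombination if upper < 0.9; else uninformative. The
likelihood assumes HWE genotype proportions, as Haploview's does, even
though the panel is highly inbred; the planted-block recovery tests
show the classifier still separates founder blocks from free
recombination on ~95%-selfed panels at n = 400.

A candidate block is a contiguous marker run whose outermost pair is
strong-LD and whose informative pairs are ≥ 95% strong-LD among
strong-LD + recombination. Haploview's size-dependent special cases for
2–4-marker blocks are deliberately collapsed into this single
informative-fraction rule; the fraction, the window, and an optional
per-pair MAF floor (default off) are parameters. Candidates are
accepted greedily by descending marker count (ties: longer bp span,
then leftmost), discarding overlaps, so the partition is deterministic
and invariant to sample order.

## Mixed-model GWAS

The single-locus LMM is `y = Xβ + g + ε`, `g ~ N(0, σ²_g K)`,
`K = ZZᵀ/m` over standardized mean-imputed dosages. K is
eigendecomposed once per panel; for each trait the variance ratio
δ = σ²_e/σ²_g is estimated by REML on the rotated profile likelihood
(grid of 41 points on log δ ∈ [−10, 10], then bounded scalar
refinement). REML rather than ML because variance components at
n ≈ 400 are noticeably biased under ML; the difference is otherwise
immaterial here. Every SNP is then given a 1-df Wald test in the
rotated model with the candidate SNP appended to the fixed effects;
the scan is vectorized through the Schur complement of the covariate
normal equations, so a 2,000-SNP panel scans in milliseconds. One
global K is reused for all candidate SNPs (no leave-one-chromosome-out)
— this matches common FaST-LMM usage; proximal contamination slightly
deflates test statistics at causal loci.

Default covariates are the top-8 genotype PCs (mean-imputed,
standardized dosages); the geographic variant appends the first 2 axes
of a classical-scaling PCoA of great-circle (haversine) distances
between collection sites, with negative eigenvalues discarded. Ordinal
phenotypes are analyzed as integer-coded linear traits — the same model
is applied to every descriptor.

Genomic control uses λ = median(χ²)/0.4549; statistics are deflated
only when λ > 1 (applied before FDR — the correction order is a
convention). q-values are Benjamini–Hochberg per trait via
`statsmodels.multipletests`, cross-checked in the tests against the
hand step-up formula.

## Haploblock enrichment

For a trait, SNPs are ranked by increasing λ-adjusted p (ties broken by
genomic coordinate) with rank statistic −log₁₀(p) capped at 300. The
running sum increments at block members by statᵅ/Σ statᵅ (α = 1 by
default; α = 0 gives the unweighted Kolmogorov–Smirnov walk, invariant
to any rank-preserving transform of p) and decrements by 1/(N−|block|)
at misses; ES is the extremum of maximal absolute deviation, ties
between equal positive and negative deviations resolving positive. If
every member statistic is 0 the hit weights fall back to uniform.

The null distribution draws random same-size SNP sets without
replacement. One permutation stream per trait produces, per
permutation, a random ordered sample of the maximal block size whose
prefixes are uniform subsets of every smaller size, so all block sizes
share the stream (memory is bounded by chunking, 4,000 permutations at
a time). Only the positive tail is tested —
p = (1 + #{ES_null ≥ ES_obs})/(n_perm + 1) — because only positive
enrichment is declared; BH FDR is applied across blocks within the
trait, and a block is significant when ES > 0 and q < 0.05. Blocks
must have strictly more than 6 SNPs to enter the test.

A caveat worth stating plainly: the random-set null treats block
members as exchangeable with independent SNPs, but members of a real
(or planted) haploblock are in strong mutual LD and share p-values, so
raw permutation p-values are mildly anticonservative under the complete
null. The BH step across blocks absorbs most of this in practice — the
acceptance suite measures the realized type-I error of the full
GWAS → enrichment chain on 20 null traits and checks it against the
nominal rate — but enrichment p-values for strongly rank-1 blocks
(few founder haplotypes, members perfectly correlated) should be read
with this in mind.

## Trait similarity and bi-clustering

The similarity of two traits is the Sørensen–Dice coefficient
2|A∩B|/(|A|+|B|) of their enriched-block sets (0 when both sets are
empty; empty-set traits get a zero row, flagged). "Bi-clustering" of
the symmetric matrix is one average-linkage hierarchical clustering of
1 − Dice applied to both axes; traits enter in alphabetical order so
tie-breaking is deterministic. Flat groups come from cutting the
dendrogram at a height threshold (default 0.8; the threshold is an
exposed parameter with no canonical value — the groups it produces
should be read alongside the dendrogram, not as an inference).

## Descriptive statistics

Spearman matrices use pairwise-complete observations with average ranks
for ties; entries with fewer than 3 complete pairs or a constant column
are reported missing. Nucleotide diversity per site is
(n/(n−1))·2p(1−p) on non-missing alleles; the per-(group, chromosome)
summary averages over sites polymorphic *within that group*, which
overestimates genome-wide diversity but is comparable between groups.
Mann–Whitney group comparisons are exact for groups of ≤ 20 without
ties, otherwise normal-approximate with tie correction.

## The synthetic-data generator

The generator emulates the statistical structure of a selfing-crop
landrace panel, not its biology:

* **Genomes.** Two gametes per sample; selfing is enforced by copying
  one gamete genome-wide with probability `selfing_inbreeding`
  (default 0.95), which reproduces the high-homozygosity dosage
  distribution without a coalescent. Background SNPs segregate freely
  with ancestral frequencies uniform on [0.05, 0.5] and Balding–Nichols
  group drift (default Fst 0.10, 6 groups). Missingness is uniform at
  random (default 3%) — no mechanism is modeled.
* **Planted blocks.** Within a planted block both gametes draw whole
  haplotypes from a founder pool with group-specific Dirichlet
  frequencies; between blocks recombination is free. Founder pools are
  built as infinite-sites mutations on a random founder genealogy:
  each SNP's derived allele arises once on a random branch, so any two
  member SNPs show at most three of the four gamete types (|D′| = 1,
  the defining property of a recombination-free haploblock) while
  allele frequencies vary across members. Independent random founder
  haplotypes would violate the four-gamete rule and be undetectable by
  a D′-CI method; two complementary founders would make all members
  perfectly correlated, which is unrealistic for a worldwide collection
  and degrades the enrichment null (see the caveat above). The standard
  benchmark panel plants 4–8 founders per block.
* **Traits.** trait = scaled causal component (per-SNP betas on planted
  blocks) + polygenic background (random non-causal SNPs,
  orthogonalized against the causal component so variance shares add)
  + Gaussian noise, rescaled so the realized genetic variance fraction
  matches the heritability target. Ordinal traits threshold the latent
  value at equal-probability quantiles. `graded_effects` supplies
  per-SNP betas (1.0, 1.2, …) because equal betas on a two-founder
  block can sum to a constant. Effect sizes are free parameters of the
  test suite — no field estimates exist for them.
* **Geography/bioclim.** Groups get real-world-plausible centroid
  coordinates with Gaussian jitter (default 1.5°); each bioclimatic
  variable is a group-level mean plus a latent factor shared within its
  correlation block (weight √0.9) plus independent noise, giving high
  within-block and low between-block rank correlations. Climate rasters
  are not emulated beyond this correlation structure.

The default study panel mirrors a real reduced-representation landrace
panel: 400 accessions, 8 chromosomes with uneven SNP counts summing to
2,579 (densest chromosome 792 SNPs, sparsest 91), chromosome lengths
16.5–59.5 Mb, 6 geographic groups. What passing tests on this generator
do **not** show: robustness to genotyping error, non-random
missingness, admixed individuals, or LD created by selection rather
than founder structure.

## Problem sizes and seeds

The acceptance suite uses benchmark sizes chosen for a single CPU: a
2,000-SNP / 40-block / n = 400 panel for calibration and power
(10,000 permutations per trait; the headline pipeline run uses the
conventional 100,000), 50 replicates for power, 25 for
pleiotropy-group recovery, 20 seeds for block recovery and GWAS
calibration. All randomness flows from one global seed through named
`SeedSequence` children, so every stage is individually reproducible;
identical configuration and seed give byte-identical output tables.

## Known limitations

* No LOCO kinship; no exact FaST-LMM low-rank tricks, proximal
  contamination handling, multi-trait or interaction models.
* The D′ likelihood assumes HWE; CI coverage on heavily inbred panels
  is approximate (block classification is robust in our tests, the CI
  itself should not be quoted as a calibrated interval).
* Four-gamete and solid-spine block definitions are not implemented.
* The enrichment null ignores intra-block LD (see above); no NES
  normalization or multilevel p refinement.
* The panel-scale counts this pipeline produces on synthetic panels
  (blocks, hits, enriched pairs) depend on the generator's settings and
  are not comparable to any particular real panel.
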