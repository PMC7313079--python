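# haplogwas

LD structure, haploblock partitioning, mixed-model GWAS and
haploblock set-enrichment for selfing crop landrace panels.

## The problem

Collections of crop landraces — locally adapted varieties gathered from
historic centers of cultivation — are genotyped at a few thousand SNPs
and scored for dozens of phenotypes, with bioclimatic variables at the
collection sites treated as *extended phenotypes*. Because landraces of
a selfing species are highly homozygous and LD decays over hundreds of
kilobases, single-SNP association results are naturally organized into
*haploblocks*: contiguous marker runs with strong mutual LD and little
evidence of historical recombination. This package implements the full
analysis chain for such panels:

1. **Marker filtering** — call rate ≥ 90%, minor allele frequency ≥ 3%.
2. **LD characterization** — dosage r² for intra-chromosomal and
   unlinked (cross-chromosome) pairs; the parametric 95th percentile of
   the unlinked distribution as the critical value; a second-degree
   LOESS of r² against distance whose crossing of the critical value
   estimates the LD decay range.
3. **Haploblock partitioning** — the Gabriel confidence-interval method
   as in Haploview: likelihood CIs on |D′| per marker pair (strong LD
   when the CI is within [0.7, 0.98], recombination when the upper
   bound is below 0.9), maximal runs dominated by strong-LD pairs.
4. **Mixed-model GWAS** — the single-locus LMM
   `y = Xβ + g + ε`, `g ~ N(0, σ²_g K)` with kinship `K = ZZᵀ/m` from
   standardized dosages, solved by one spectral decomposition per panel
   and a per-trait REML profile over δ = σ²_e/σ²_g; the first 8
   genotype PCs as covariates (optionally plus 2 axes of a geographic
   PCoA on great-circle distances); genomic control λ_GC and
   Benjamini–Hochberg FDR per trait.
5. **Haploblock enrichment** — the package's central test: for each
   trait, all SNPs are ranked by increasing GWAS p-value and each
   haploblock (> 6 SNPs) is scored with a GSEA-style weighted running
   sum; the enrichment score ES is the signed maximal deviation of that
   walk. Significance comes from permutation over random same-size SNP
   sets (positive tail, default 100,000 permutations) with BH FDR
   across blocks; a block is *enriched* when ES > 0 and q < 0.05.
6. **Trait bi-clustering** — traits are compared by the Sørensen–Dice
   overlap of their enriched-block sets, `2|A∩B| / (|A|+|B|)`, and the
   symmetric similarity matrix is hierarchically clustered (average
   linkage on 1 − Dice) on both axes to reveal groups of traits sharing
   genetic architecture (candidate pleiotropy / co-adapted complexes).

A first-class synthetic-data generator produces panels with the
statistical structure this analysis assumes — selfing genomes, planted
founder-haplotype blocks, geographic group structure, correlated
bioclimatic covariates, and traits with causal SNPs concentrated in
designated blocks — plus ground-truth records for recovery testing.

## Worked example

```python
from haplogwas.simulate import (SimConfig, PlantedBlock, TraitSpec,
                                simulate_genotypes, simulate_traits,
                                graded_effects, truth_haploblocks)
from haplogwas import gwas, ld, enrichment as enr

cfg = SimConfig(
    n_samples=400,
    chromosomes=(("Ca1", 8_000_000, 40), ("Ca2", 8_000_000, 30)),
    block_spec=(PlantedBlock("Ca1", 1_000_000, 1_200_000, 8, 4),
                PlantedBlock("Ca2", 2_000_000, 2_300_000, 8, 4)),
    missing_rate=0.0, seed=7,
)
gm, truth = simulate_genotypes(cfg)
blocks = ld.partition_haploblocks(gm)

spec = TraitSpec("yield", (("Ca1_B1", graded_effects(8)),),
                 heritability_target=0.3)
traits = simulate_traits(gm, truth, [spec], seed=1)
pcs = gwas.genotype_pca(gm, k=8)
res = gwas.gwas_scan(gm, traits["yield"].to_numpy(), pcs, method="lmm")
ranked = enr.rank_snps(res)
result = enr.permutation_test(ranked, truth_haploblocks(truth),
                              n_perm=100_000, seed=2)
```

prints (via the accompanying report lines):

```
panel: 400 samples x 70 SNPs
  inferred Ca1_block1: 8 SNPs at 1,000,000-1,200,000 bp
  inferred Ca2_block1: 8 SNPs at 2,000,000-2,300,000 bp
GWAS: lambda_GC = 0.80; top SNP Ca1:1171429 q = 2.48e-06
  Ca1_B1: ES = +0.98, q = 0.0000  ENRICHED
  Ca2_B1: ES = +0.66, q = 0.4322  -
```

Both planted blocks are recovered exactly by the D′-CI partition; the
block that carries 30% of the trait variance is declared enriched
(ES ≈ 1: all its SNPs sit at the very top of the ranking) while the
neutral block is not.

## The analysis scripts

`analysis/01_simulate_panel.py` … `08_descriptive_stats.py` run the
whole study on the default synthetic panel (≈2,579 SNPs on 8
chromosomes, 400 accessions, 40 planted blocks, 10 phenotypes and 19
bioclimatic variables), writing every table under `results/analysis/`.
Each script prints a short narrative of what it found; run them in
order.

The same stages are exposed as a CLI (`haplogwas simulate|filter|ld|
blocks|gwas|enrich|similarity|run-all`) over a YAML configuration, and
as library functions in `haplogwas.pipeline`.

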