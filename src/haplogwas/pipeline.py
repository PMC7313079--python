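"""End-to-end pipeline: simulate-or-ingest -> filter -> LD/blocks ->
GWAS -> haploblock enrichment -> trait similarity.

Every stage writes its tables under the output directory and can be
re-run individually from the saved intermediates; ``run_pipeline`` chains
them and writes a JSON manifest plus a run log with all resolved
parameters and child seeds. All randomness flows from the global seed
via named child seeds, so stages are individually reproducible.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import genio, gwas as assoc, ld, similarity as simm, simulate as sim

logger = logging.getLogger(__name__)

STAGES = ["simulate", "filter", "ld", "blocks", "gwas", "enrich", "similarity"]


@dataclass
class PipelineConfig:
    """Declarative configuration; every analysis default is overridable."""

    outdir: str = "results/pipeline"
    seed: int = 0
    # input mode: either the three paths, or simulate=True
    vcf: str | None = None
    traits_file: str | None = None
    coords_file: str | None = None
    simulate: bool = True
    n_samples: int = 400
    n_planted_blocks_per_chrom: int = 5
    # marker filter
    min_call_rate: float = 0.90
    min_maf: float = 0.03
    # LD
    max_pairs: int = 100_000
    loess_span: float = 0.3
    critical_percentile: float = 0.95
    critical_mode: str = "parametric_normal"
    # blocks
    max_block_span_bp: int = 500_000
    informative_fraction: float = 0.95
    min_pair_maf: float = 0.0
    # covariates / GWAS
    n_pcs: int = 8
    use_geo_pcoa: bool = False
    n_pcoa: int = 2
    gwas_method: str = "lmm"
    # enrichment
    min_snps_exclusive: int = 6
    n_perm: int = 100_000
    fdr: float = 0.05
    alpha: float = 1.0
    # clustering
    height_threshold: float = 0.8

    def __post_init__(self) -> None:
        has_paths = self.vcf is not None
        if has_paths and self.simulate:
            raise ValueError("provide either input paths or simulate=True, not both")
        if not has_paths and not self.simulate:
            raise ValueError("no input: set simulate=True or provide a VCF")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def child_seeds(self) -> dict[str, int]:
        names = ["simulate", "traits", "geography", "unlinked_pairs",
                 "intra_pairs", "permutations"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: int(c.generate_state(1)[0] % (2**31))
                for n, c in zip(names, children)}


def default_scenario(
    n_samples: int = 400,
    seed: int = 0,
    blocks_per_chrom: int = 5,
    chromosomes=None,
) -> tuple[sim.SimConfig, list[sim.TraitSpec]]:
    """The default synthetic study: a chickpea-like panel with planted
    pleiotropic haploblocks.

    Plants ``blocks_per_chrom`` founder-haplotype blocks per chromosome
    (8-12 SNPs, 150-400 kb, 2-4 founders) and defines ten traits: two
    pleiotropy groups of three traits sharing two causal blocks each, two
    independent single-block traits, and two null traits.
    """
    rng = np.random.default_rng(seed)
    if chromosomes is None:
        chromosomes = sim.CHICKPEA_CHROMOSOMES
    blocks = []
    for chrom, length, n_snps in chromosomes:
        nb = min(blocks_per_chrom, max(n_snps // 16, 1))
        starts = np.linspace(0.08, 0.85, nb) * length
        for s in starts:
            span = int(rng.integers(150_000, 400_000))
            blocks.append(
                sim.PlantedBlock(
                    chrom=chrom,
                    start_bp=int(s),
                    end_bp=int(s) + span,
                    n_snps=int(rng.integers(8, 13)),
                    # worldwide landrace panels carry several common
                    # haplotypes per block
                    n_founder_haplotypes=int(rng.integers(4, 9)),
                )
            )
    config = sim.SimConfig(
        n_samples=n_samples,
        chromosomes=tuple(chromosomes),
        block_spec=tuple(blocks),
        seed=seed,
    )
    # block ids are {chrom}_B{k} in planting order per chromosome
    ids_by_chrom: dict[str, list[str]] = {}
    size_by_id: dict[str, int] = {}
    for b in blocks:
        bid = f"{b.chrom}_B{len(ids_by_chrom.setdefault(b.chrom, [])) + 1}"
        ids_by_chrom[b.chrom].append(bid)
        size_by_id[bid] = b.n_snps

    def ramp(bid: str) -> tuple[float, ...]:
        # graded per-SNP effects; avoids cancellation between complementary
        # founder haplotypes
        return tuple(1.0 + 0.2 * k for k in range(size_by_id[bid]))

    all_ids = [i for ids in ids_by_chrom.values() for i in ids]
    groups = [all_ids[0:2], all_ids[2:4]]
    specs = []
    for gi, gblocks in enumerate(groups, start=1):
        for t in range(3):
            specs.append(
                sim.TraitSpec(
                    trait_name=f"group{gi}_trait{t + 1}",
                    causal_blocks=tuple((b, ramp(b)) for b in gblocks),
                    heritability_target=0.4,
                )
            )
    for t, bid in enumerate(all_ids[4:6], start=1):
        specs.append(
            sim.TraitSpec(
                trait_name=f"solo_trait{t}",
                causal_blocks=((bid, ramp(bid)),),
                heritability_target=0.3,
            )
        )
    specs.append(sim.TraitSpec("null_trait1", (), 0.0))
    specs.append(sim.TraitSpec("null_trait2", (), 0.0))
    return config, specs


def _out(outdir: str | Path) -> Path:
    p = Path(outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def stage_simulate(cfg: PipelineConfig) -> dict[str, str]:
    out = _out(cfg.outdir)
    seeds = cfg.child_seeds()
    config, specs = default_scenario(
        n_samples=cfg.n_samples, seed=seeds["simulate"],
        blocks_per_chrom=cfg.n_planted_blocks_per_chrom,
    )
    gm, truth = sim.simulate_genotypes(config)
    phenos = sim.simulate_traits(gm, truth, specs, seed=seeds["traits"])
    coords, bioclim = sim.simulate_geography_bioclim(
        gm, truth, seed=seeds["geography"]
    )
    traits = pd.concat([phenos, bioclim], axis=1)
    genio.write_vcf(gm, out / "genotypes.vcf")
    sim.write_trait_table(traits, out / "traits.tsv")
    sim.write_trait_table(coords, out / "coords.tsv")
    truth.to_json(out / "truth.json")
    return {
        "genotypes": str(out / "genotypes.vcf"),
        "traits": str(out / "traits.tsv"),
        "coords": str(out / "coords.tsv"),
        "truth": str(out / "truth.json"),
    }


def _load_inputs(cfg: PipelineConfig, filtered: bool = True):
    out = _out(cfg.outdir)
    vcf = out / "filtered.vcf" if filtered else None
    if vcf is None or not vcf.exists():
        vcf = Path(cfg.vcf) if cfg.vcf else out / "genotypes.vcf"
    gm = genio.read_vcf(str(vcf))
    traits = sim.read_trait_table(cfg.traits_file or out / "traits.tsv")
    coords = sim.read_trait_table(cfg.coords_file or out / "coords.tsv")
    traits = traits.loc[gm.sample_ids]
    coords = coords.loc[gm.sample_ids]
    return gm, traits, coords


def stage_filter(cfg: PipelineConfig) -> dict[str, str]:
    out = _out(cfg.outdir)
    src = Path(cfg.vcf) if cfg.vcf else out / "genotypes.vcf"
    gm = genio.read_vcf(str(src))
    spec = genio.VariantFilterSpec(cfg.min_call_rate, cfg.min_maf)
    fgm = genio.filter_variants(gm, spec)
    genio.write_vcf(fgm, out / "filtered.vcf")
    genio.write_dosage_table(fgm, out / "dosages.tsv")
    genio.snp_density(fgm, 1_000_000).to_csv(
        out / "snp_density.tsv", sep="\t", index=False
    )
    logger.info("filter: %d -> %d variants", gm.n_variants, fgm.n_variants)
    return {
        "filtered_vcf": str(out / "filtered.vcf"),
        "dosages": str(out / "dosages.tsv"),
        "snp_density": str(out / "snp_density.tsv"),
    }


def stage_ld(cfg: PipelineConfig) -> dict[str, str]:
    out = _out(cfg.outdir)
    gm, _traits, _coords = _load_inputs(cfg)
    seeds = cfg.child_seeds()
    unlinked = ld.pairwise_r2(gm, "unlinked", cfg.max_pairs, seeds["unlinked_pairs"])
    crit = ld.unlinked_critical_r2(unlinked, cfg.critical_percentile,
                                   cfg.critical_mode)
    intra = ld.pairwise_r2(gm, "intra_chromosomal", cfg.max_pairs,
                           seeds["intra_pairs"])
    fit = ld.fit_ld_decay(intra, crit, cfg.loess_span)
    intra.to_csv(out / "ld_intra_pairs.tsv", sep="\t", index=False)
    fit.curve.to_csv(out / "ld_decay_curve.tsv", sep="\t", index=False)
    with open(out / "ld_summary.json", "w") as fh:
        json.dump(
            {
                "critical_r2": crit,
                "critical_mode": cfg.critical_mode,
                "decay_range_bp": fit.decay_range_bp,
                "n_unlinked_pairs": int(len(unlinked)),
                "n_intra_pairs": int(len(intra)),
            },
            fh, indent=1,
        )
    return {
        "ld_intra_pairs": str(out / "ld_intra_pairs.tsv"),
        "ld_decay_curve": str(out / "ld_decay_curve.tsv"),
        "ld_summary": str(out / "ld_summary.json"),
    }


def stage_blocks(cfg: PipelineConfig) -> dict[str, str]:
    out = _out(cfg.outdir)
    gm, _traits, _coords = _load_inputs(cfg)
    blocks = ld.partition_haploblocks(
        gm, cfg.max_block_span_bp, cfg.informative_fraction,
        min_pair_maf=cfg.min_pair_maf,
    )
    ld.write_blocks_text(blocks, out / "blocks.tsv")
    ld.write_blocks_bed(blocks, out / "blocks.bed")
    logger.info("blocks: %d blocks, %d SNPs",
                len(blocks), sum(b.n_snps for b in blocks))
    return {"blocks": str(out / "blocks.tsv"), "blocks_bed": str(out / "blocks.bed")}


def stage_gwas(cfg: PipelineConfig) -> dict[str, str]:
    out = _out(cfg.outdir)
    gm, traits, coords = _load_inputs(cfg)
    cov = assoc.genotype_pca(gm, cfg.n_pcs)
    if cfg.use_geo_pcoa:
        cov = assoc.merge_covariates(cov, assoc.geographic_pcoa(coords, cfg.n_pcoa))
    results = assoc.gwas_many(gm, traits, cov, method=cfg.gwas_method)
    gdir = _out(out / "gwas")
    summary = []
    for name, res in results.items():
        res.table.to_csv(gdir / f"{name}.tsv", sep="\t", index=False)
        summary.append((name, res.lambda_gc, res.delta, res.n_hits))
    pd.DataFrame(
        summary, columns=["trait", "lambda_gc", "delta", "n_hits_q05"]
    ).to_csv(out / "gwas_summary.tsv", sep="\t", index=False)
    cov_df = pd.DataFrame(
        cov.matrix, index=gm.sample_ids,
        columns=[f"{cov.source}_{i + 1}" for i in range(cov.k)],
    )
    cov_df.to_csv(out / "covariates.tsv", sep="\t", index_label="sample")
    # both counting units for "hits": SNP-trait pairs and unique SNPs
    pairs = sum(r.n_hits for r in results.values())
    snps = len(
        {
            (row.chrom, row.pos)
            for r in results.values()
            for row in r.table[r.table["q"] < 0.05].itertuples(index=False)
        }
    )
    with open(out / "gwas_hits.json", "w") as fh:
        json.dump({"snp_trait_pairs_q05": pairs, "unique_snps_q05": snps}, fh)
    return {
        "gwas_dir": str(gdir),
        "gwas_summary": str(out / "gwas_summary.tsv"),
        "covariates": str(out / "covariates.tsv"),
        "gwas_hits": str(out / "gwas_hits.json"),
    }


def stage_enrich(cfg: PipelineConfig) -> dict[str, str]:
    out = _out(cfg.outdir)
    blocks = enr.filter_blocks(
        ld.read_blocks_text(out / "blocks.tsv"), cfg.min_snps_exclusive
    )
    gdir = out / "gwas"
    if not gdir.exists():
        raise FileNotFoundError("no GWAS results found; run the gwas stage first")
    seeds = cfg.child_seeds()
    frames = []
    sets: dict[str, set[str]] = {}
    for f in sorted(gdir.glob("*.tsv")):
        name = f.stem
        table = pd.read_csv(f, sep="\t")
        res = assoc.GWASResult(name, table)
        if blocks:
            ranked = enr.rank_snps(res)
            trait_seed = (seeds["permutations"] + zlib.crc32(name.encode())) % (2**31)
            df = enr.permutation_test(
                ranked, blocks, n_perm=cfg.n_perm, seed=trait_seed,
                alpha=cfg.alpha, fdr=cfg.fdr,
            )
        else:
            df = pd.DataFrame(columns=enr.ENRICHMENT_COLUMNS)
        frames.append(df)
        sets[name] = set(df.loc[df["significant"], "block_id"])
    result = (
        pd.concat(frames, ignore_index=True)
        if frames else pd.DataFrame(columns=enr.ENRICHMENT_COLUMNS)
    )
    result.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    with open(out / "enriched_sets.json", "w") as fh:
        json.dump({k: sorted(v) for k, v in sets.items()}, fh, indent=1)
    return {
        "enrichment": str(out / "enrichment.tsv"),
        "enriched_sets": str(out / "enriched_sets.json"),
    }


def stage_similarity(cfg: PipelineConfig) -> dict[str, str]:
    out = _out(cfg.outdir)
    with open(out / "enriched_sets.json") as fh:
        sets = {k: set(v) for k, v in json.load(fh).items()}
    sm = simm.bicluster(simm.similarity_matrix(sets),
                        height_threshold=cfg.height_threshold)
    sm.to_frame().to_csv(out / "similarity.tsv", sep="\t", index_label="trait")
    sm.to_long().to_csv(out / "similarity_long.tsv", sep="\t", index=False)
    with open(out / "dendrogram.nwk", "w") as fh:
        fh.write(simm.dendrogram_newick(sm) + "\n")
    with open(out / "trait_groups.json", "w") as fh:
        json.dump(simm.flat_groups(sm, cfg.height_threshold), fh, indent=1)
    return {
        "similarity": str(out / "similarity.tsv"),
        "similarity_long": str(out / "similarity_long.tsv"),
        "dendrogram": str(out / "dendrogram.nwk"),
        "trait_groups": str(out / "trait_groups.json"),
    }


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "filter": stage_filter,
    "ld": stage_ld,
    "blocks": stage_blocks,
    "gwas": stage_gwas,
    "enrich": stage_enrich,
    "similarity": stage_similarity,
}


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the requested stages in order; returns the output manifest."""
    out = _out(cfg.outdir)
    if stages is None:
        stages = [s for s in STAGES if s != "simulate" or cfg.simulate]
    manifest: dict = {"outputs": {}, "stages_run": [], "config": asdict(cfg),
                      "child_seeds": cfg.child_seeds()}
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.time()
        try:
            outputs = _STAGE_FUNCS[stage](cfg)
        except Exception as exc:
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=1)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["outputs"].update(outputs)
        manifest["stages_run"].append({"stage": stage,
                                       "seconds": round(time.time() - t0, 2)})
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    with open(out / "run_log.json", "w") as fh:
        json.dump({"config": asdict(cfg), "child_seeds": cfg.child_seeds()},
                  fh, indent=1)
    return manifest
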