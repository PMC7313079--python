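"""Synthetic landrace panels: genotypes, traits, geography, bioclim.

The generator emulates a selfing crop landrace panel: a few hundred
largely homozygous accessions on 8 chromosomes with uneven SNP density,
strong localized LD inside planted founder-haplotype blocks, free
recombination between blocks, geographic population structure, correlated
bioclimatic covariates at collection sites, and traits whose causal SNPs
are concentrated in designated haploblocks (optionally shared across
traits, i.e. planted pleiotropy).

Every sample carries two gametes; selfing is enforced by copying one
gamete genome-wide with probability ``selfing_inbreeding``, which
reproduces the high-homozygosity dosage distribution without a full
coalescent. Group structure comes from Balding–Nichols drift of
background allele frequencies and group-specific founder-haplotype
frequencies inside blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, VARIANT_COLUMNS

# Chromosome sizes (bp) of the reference chickpea assembly; Ca6 is the
# longest (59.46 Mb) and Ca8 the shortest (16.48 Mb).
CHICKPEA_CHROMOSOMES: list[tuple[str, int, int]] = [
    ("Ca1", 48_360_000, 356),
    ("Ca2", 36_630_000, 280),
    ("Ca3", 39_990_000, 330),
    ("Ca4", 49_190_000, 792),
    ("Ca5", 48_170_000, 270),
    ("Ca6", 59_460_000, 300),
    ("Ca7", 48_960_000, 160),
    ("Ca8", 16_480_000, 91),
]


@dataclass(frozen=True)
class PlantedBlock:
    """A founder-haplotype block to plant on a chromosome."""

    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_founder_haplotypes: int

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("block needs at least one SNP")
        if self.end_bp < self.start_bp:
            raise ValueError("block end before start")
        if self.n_snps < 64 and self.n_founder_haplotypes > 2 ** self.n_snps:
            raise ValueError(
                f"{self.n_founder_haplotypes} founder haplotypes cannot be "
                f"distinct over {self.n_snps} SNPs"
            )


@dataclass(frozen=True)
class SimConfig:
    """Panel-level simulation settings (the study conditions)."""

    n_samples: int = 400
    chromosomes: tuple[tuple[str, int, int], ...] = tuple(CHICKPEA_CHROMOSOMES)
    block_spec: tuple[PlantedBlock, ...] = ()
    selfing_inbreeding: float = 0.95
    missing_rate: float = 0.03
    n_groups: int = 6
    fst: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for frac, name in (
            (self.selfing_inbreeding, "selfing_inbreeding"),
            (self.missing_rate, "missing_rate"),
            (self.fst, "fst"),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        by_chrom: dict[str, list[PlantedBlock]] = {}
        names = {c[0] for c in self.chromosomes}
        for name, _length, n_snps in self.chromosomes:
            if n_snps < 1:
                raise ValueError(f"chromosome {name} needs at least 1 SNP")
        for b in self.block_spec:
            if b.chrom not in names:
                raise ValueError(f"block on unknown chromosome {b.chrom}")
            by_chrom.setdefault(b.chrom, []).append(b)
        for chrom, blocks in by_chrom.items():
            blocks = sorted(blocks, key=lambda b: b.start_bp)
            for a, b in zip(blocks, blocks[1:]):
                if b.start_bp <= a.end_bp:
                    raise ValueError(f"overlapping planted blocks on {chrom}")
            (_, _length, n_snps) = next(c for c in self.chromosomes if c[0] == chrom)
            if sum(b.n_snps for b in blocks) > n_snps:
                raise ValueError(f"planted blocks exceed SNP budget on {chrom}")


@dataclass(frozen=True)
class TraitSpec:
    """A simulated trait: causal blocks, heritability, type."""

    trait_name: str
    # (block id, effect): effect is one beta for every member SNP, or a
    # sequence of per-SNP betas matching the block size
    causal_blocks: tuple = ()
    heritability_target: float = 0.5
    polygenic_share: float = 0.0
    trait_type: str = "quantitative"  # or "ordinal"
    n_levels: int = 5  # ordinal levels

    def __post_init__(self) -> None:
        if not 0.0 <= self.heritability_target <= 1.0:
            raise ValueError("heritability_target must be in [0, 1]")
        if not 0.0 <= self.polygenic_share <= 1.0:
            raise ValueError("polygenic_share must be in [0, 1]")
        if self.trait_type not in ("quantitative", "ordinal"):
            raise ValueError(f"unknown trait_type {self.trait_type}")


@dataclass
class GroundTruth:
    """What was planted: block layout, group labels, causal sets."""

    block_variants: dict[str, list[int]]  # block id -> variant indices
    block_bounds: dict[str, tuple[str, int, int]]  # id -> (chrom, start, end)
    group_labels: list[int]
    causal_snps: dict[str, list[int]] = field(default_factory=dict)
    variance_components: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _founder_pool(rng: np.random.Generator, n_snps: int, n_founders: int) -> np.ndarray:
    """Founder haplotypes from infinite-sites mutations on a random genealogy.

    Each SNP's derived allele arises once, on a random branch of a random
    coalescent-style tree over the founders, so carrier sets are nested or
    disjoint. Any two block SNPs therefore show at most three of the four
    gamete types (|D'| = 1, the defining property of a recombination-free
    haploblock) while allele frequencies differ across members.
    """
    pool = np.zeros((n_founders, n_snps), dtype=np.int8)
    if n_founders == 1:
        return pool
    clades: list[frozenset[int]] = [frozenset([i]) for i in range(n_founders)]
    active = [frozenset([i]) for i in range(n_founders)]
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        merged = active[i] | active[j]
        active = [c for t, c in enumerate(active) if t not in (i, j)]
        active.append(merged)
        if len(merged) < n_founders:
            clades.append(merged)
    for s in range(n_snps):
        clade = clades[int(rng.integers(len(clades)))]
        pool[list(clade), s] = 1
    return pool


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, GroundTruth]:
    """Generate the genotype panel and its ground-truth record.

    Within each planted block both gametes of a sample are drawn from a
    small founder pool (group-weighted), creating strong within-block LD;
    background SNPs segregate independently with Balding–Nichols
    group-specific frequencies. Deterministic for a fixed config.
    """
    rng_pos, rng_geno, rng_founder, rng_miss, _ = _child_rngs(config.seed, 5)

    n = config.n_samples
    # contiguous, roughly equal geographic groups
    groups = np.sort(np.arange(n) % config.n_groups)

    blocks_by_chrom: dict[str, list[PlantedBlock]] = {}
    for b in config.block_spec:
        blocks_by_chrom.setdefault(b.chrom, []).append(b)

    variant_rows: list[tuple] = []
    gamete1_cols: list[np.ndarray] = []
    gamete2_cols: list[np.ndarray] = []
    block_variants: dict[str, list[int]] = {}
    block_bounds: dict[str, tuple[str, int, int]] = {}

    selfed = rng_geno.random(n) < config.selfing_inbreeding

    for chrom, length, n_snps in config.chromosomes:
        blocks = sorted(blocks_by_chrom.get(chrom, []), key=lambda b: b.start_bp)
        n_background = n_snps - sum(b.n_snps for b in blocks)
        # background positions avoid planted intervals
        forbidden = [(b.start_bp, b.end_bp) for b in blocks]
        bg_pos: list[int] = []
        while len(bg_pos) < n_background:
            cand = rng_pos.integers(1, length + 1, size=2 * n_background + 8)
            for p in cand:
                if any(s <= p <= e for s, e in forbidden):
                    continue
                bg_pos.append(int(p))
                if len(bg_pos) == n_background:
                    break
        entries: list[tuple[int, str, int]] = [(p, "bg", -1) for p in set(bg_pos)]
        # rejection-sample replacements for duplicate background positions
        while len(entries) < n_background:
            p = int(rng_pos.integers(1, length + 1))
            if any(s <= p <= e for s, e in forbidden) or any(
                e[0] == p for e in entries
            ):
                continue
            entries.append((p, "bg", -1))

        for bi, b in enumerate(blocks):
            span = b.end_bp - b.start_bp
            if b.n_snps == 1:
                bpos = np.array([b.start_bp])
            else:
                bpos = b.start_bp + np.round(
                    np.linspace(0, span, b.n_snps)
                ).astype(int)
                bpos = np.unique(bpos)
                while len(bpos) < b.n_snps:  # tiny spans: fill adjacent bp
                    extra = int(rng_pos.integers(b.start_bp, b.end_bp + 1))
                    bpos = np.unique(np.append(bpos, extra))
            for k, p in enumerate(bpos[: b.n_snps]):
                entries.append((int(p), f"{chrom}_B{bi + 1}", k))

        entries.sort(key=lambda t: t[0])

        # pre-draw per-block gamete founder assignments
        block_gametes: dict[str, np.ndarray] = {}
        for bi, b in enumerate(blocks):
            bid = f"{chrom}_B{bi + 1}"
            pool = _founder_pool(rng_founder, b.n_snps, b.n_founder_haplotypes)
            # group-specific founder frequencies (drifted Dirichlet)
            conc = max((1.0 - config.fst) / max(config.fst, 1e-6), 0.2)
            w = rng_geno.dirichlet(np.full(b.n_founder_haplotypes, conc), size=config.n_groups)
            f1 = np.empty((n, b.n_snps), dtype=np.int8)
            f2 = np.empty((n, b.n_snps), dtype=np.int8)
            for g in range(config.n_groups):
                idx = np.flatnonzero(groups == g)
                pick1 = rng_geno.choice(b.n_founder_haplotypes, size=idx.size, p=w[g])
                pick2 = rng_geno.choice(b.n_founder_haplotypes, size=idx.size, p=w[g])
                f1[idx] = pool[pick1]
                f2[idx] = pool[pick2]
            block_gametes[bid] = np.stack([f1, f2])

        block_cursor: dict[str, int] = {}
        for pos, tag, k in entries:
            if tag == "bg":
                p_anc = rng_geno.uniform(0.05, 0.5)
                if config.fst > 0:
                    a = p_anc * (1 - config.fst) / config.fst
                    bpar = (1 - p_anc) * (1 - config.fst) / config.fst
                    p_grp = rng_geno.beta(a, bpar, size=config.n_groups)
                else:
                    p_grp = np.full(config.n_groups, p_anc)
                p_sample = p_grp[groups]
                g1 = (rng_geno.random(n) < p_sample).astype(np.int8)
                g2 = (rng_geno.random(n) < p_sample).astype(np.int8)
            else:
                g1 = block_gametes[tag][0][:, k]
                g2 = block_gametes[tag][1][:, k]
                block_variants.setdefault(tag, []).append(len(variant_rows))
            gamete1_cols.append(g1)
            gamete2_cols.append(g2)
            variant_rows.append((chrom, pos, "A", "G"))

        for bi, b in enumerate(blocks):
            block_bounds[f"{chrom}_B{bi + 1}"] = (chrom, b.start_bp, b.end_bp)

    g1 = np.column_stack(gamete1_cols)
    g2 = np.column_stack(gamete2_cols)
    g2[selfed] = g1[selfed]
    dosages = (g1 + g2).astype(float)

    if config.missing_rate > 0:
        miss = rng_miss.random(dosages.shape) < config.missing_rate
        dosages[miss] = np.nan

    sample_ids = [f"S{i:04d}" for i in range(n)]
    variants = pd.DataFrame(variant_rows, columns=VARIANT_COLUMNS)
    gm = GenotypeMatrix(dosages, sample_ids, variants)
    truth = GroundTruth(
        block_variants={k: sorted(v) for k, v in block_variants.items()},
        block_bounds=block_bounds,
        group_labels=groups.tolist(),
    )
    return gm, truth


def _imputed_dosages(gm: GenotypeMatrix) -> np.ndarray:
    d = gm.dosages.copy()
    col_mean = np.nanmean(d, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(d))
    d[nan_r, nan_c] = col_mean[nan_c]
    return d


def simulate_traits(
    gm: GenotypeMatrix,
    truth: GroundTruth,
    specs: list[TraitSpec],
    seed: int,
    n_polygenic_snps: int = 100,
) -> pd.DataFrame:
    """Simulate traits from planted causal blocks.

    trait = sum(beta_j * dosage_j) + polygenic background + Gaussian noise,
    with components rescaled so the realized genetic variance fraction
    matches ``heritability_target`` (split causal/polygenic by
    ``polygenic_share``). Ordinal traits threshold the latent value at
    equal-probability quantiles. Updates ``truth`` with causal indices and
    variance components in place.
    """
    rng = np.random.default_rng(seed)
    d = _imputed_dosages(gm)
    n = gm.n_samples
    out: dict[str, np.ndarray] = {}
    for spec in specs:
        causal_idx: list[int] = []
        betas: list[float] = []
        for block_id, beta in spec.causal_blocks:
            if block_id not in truth.block_variants:
                raise KeyError(f"unknown planted block {block_id}")
            members = truth.block_variants[block_id]
            per_snp = (
                [float(beta)] * len(members)
                if np.isscalar(beta)
                else [float(b) for b in beta]
            )
            if len(per_snp) != len(members):
                raise ValueError(
                    f"{block_id}: {len(per_snp)} effects for {len(members)} SNPs"
                )
            causal_idx.extend(members)
            betas.extend(per_snp)
        h2 = spec.heritability_target
        causal_share = h2 * (1.0 - spec.polygenic_share)
        poly_share = h2 * spec.polygenic_share
        if h2 > 0 and not causal_idx and spec.polygenic_share == 0:
            raise ValueError(
                f"trait {spec.trait_name}: positive heritability with no causal SNPs"
            )

        genetic = np.zeros(n)
        if causal_idx and causal_share > 0:
            c = d[:, causal_idx] @ np.asarray(betas)
            v = c.var()
            if v <= 0:
                raise ValueError(
                    f"trait {spec.trait_name}: causal component has zero variance"
                )
            genetic += (c - c.mean()) * np.sqrt(causal_share / v)
        if poly_share > 0:
            pool = np.setdiff1d(np.arange(gm.n_variants), np.asarray(causal_idx, int))
            bg = rng.choice(pool, size=min(n_polygenic_snps, pool.size), replace=False)
            pg = d[:, bg] @ rng.normal(0, 1, size=bg.size)
            pg -= pg.mean()
            if genetic.var() > 0:  # orthogonalize so variance shares add up
                c0 = genetic - genetic.mean()
                pg -= c0 * (pg @ c0) / (c0 @ c0)
            v = pg.var()
            if v > 0:
                genetic += pg * np.sqrt(poly_share / v)
        noise = rng.normal(0.0, np.sqrt(max(1.0 - h2, 1e-12)), size=n)
        latent = genetic + noise
        if spec.trait_type == "ordinal":
            qs = np.quantile(latent, np.linspace(0, 1, spec.n_levels + 1)[1:-1])
            values = np.searchsorted(qs, latent).astype(float)
        else:
            values = latent
        out[spec.trait_name] = values
        truth.causal_snps[spec.trait_name] = causal_idx
        truth.variance_components[spec.trait_name] = {
            "causal": causal_share, "polygenic": poly_share, "noise": 1.0 - h2,
        }
    return pd.DataFrame(out, index=gm.sample_ids)


# rough centroids of six historic cultivation regions (lat, lon)
_DEFAULT_CENTROIDS = np.array(
    [
        (39.0, 35.0),   # Anatolia
        (23.0, 78.0),   # India
        (9.0, 39.0),    # Ethiopia
        (41.0, 64.0),   # Central Asia
        (32.0, -6.0),   # Morocco
        (33.9, 35.9),   # Lebanon
    ]
)

DEFAULT_BIOCLIM_BLOCKS: tuple[tuple[int, ...], ...] = (
    (0, 3, 4, 5, 6),        # temperature level
    (7, 8, 9, 10),          # wet-season precipitation
    (2, 11, 12, 13),        # temperature range / seasonality
    (14, 15, 16),           # dry-season precipitation
    (17,), (18,),           # weakly-correlated singletons
)


def simulate_geography_bioclim(
    gm: GenotypeMatrix,
    truth: GroundTruth,
    n_bioclim: int = 19,
    correlation_blocks: tuple[tuple[int, ...], ...] | None = None,
    within_block_r: float = 0.9,
    jitter_deg: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collection-site coordinates and correlated bioclim covariates.

    Samples get their group's centroid plus Gaussian jitter; each bioclim
    variable is a group-level mean plus a shared within-correlation-block
    latent factor (weight sqrt(within_block_r)) plus independent noise, so
    variables in one block are strongly mutually rank-correlated and
    nearly independent across blocks.
    """
    groups = np.asarray(truth.group_labels)
    n_groups = groups.max() + 1
    if n_groups < 2:
        raise ValueError("group-structured bioclim requires at least 2 groups")
    if correlation_blocks is None:
        correlation_blocks = tuple(
            tuple(i for i in blk if i < n_bioclim) for blk in DEFAULT_BIOCLIM_BLOCKS
        )
        covered = {i for blk in correlation_blocks for i in blk}
        correlation_blocks = tuple(b for b in correlation_blocks if b) + tuple(
            (i,) for i in range(n_bioclim) if i not in covered
        )
    flat = [i for blk in correlation_blocks for i in blk]
    if sorted(flat) != list(range(n_bioclim)):
        raise ValueError("correlation_blocks must partition range(n_bioclim)")

    rng = np.random.default_rng(seed)
    cent = _DEFAULT_CENTROIDS[
        rng.choice(len(_DEFAULT_CENTROIDS), size=n_groups,
                   replace=n_groups > len(_DEFAULT_CENTROIDS))
    ]
    lat = cent[groups, 0] + rng.normal(0, jitter_deg, size=groups.size)
    lon = cent[groups, 1] + rng.normal(0, jitter_deg, size=groups.size)
    coords = pd.DataFrame({"lat": lat, "lon": lon}, index=gm.sample_ids)

    values = np.empty((groups.size, n_bioclim))
    for blk in correlation_blocks:
        group_mean = rng.normal(0, 1.0, size=n_groups)  # shared block climate
        factor = group_mean[groups] + rng.normal(0, 0.5, size=groups.size)
        factor = (factor - factor.mean()) / factor.std()
        for i in blk:
            scale = rng.uniform(0.5, 2.0)
            shift = rng.uniform(-1, 1)
            eps = rng.normal(0, 1, size=groups.size)
            v = np.sqrt(within_block_r) * factor + np.sqrt(1 - within_block_r) * eps
            values[:, i] = shift + scale * v
    names = [f"BIO{i + 1}" for i in range(n_bioclim)]
    bioclim = pd.DataFrame(values, columns=names, index=gm.sample_ids)
    return coords, bioclim


def standard_panel_config(
    seed: int,
    n_samples: int = 400,
    n_chromosomes: int = 8,
    snps_per_chrom: int = 250,
    blocks_per_chrom: int = 5,
    chrom_length_bp: int = 40_000_000,
    block_snps: tuple[int, int] = (8, 13),
    founders: tuple[int, int] = (4, 9),
) -> SimConfig:
    """A benchmark panel: equal-density chromosomes with evenly spaced
    planted founder-haplotype blocks (sizes and founder counts drawn
    uniformly from the given ranges)."""
    rng = np.random.default_rng(seed)
    chroms = tuple(
        (f"Ca{i + 1}", chrom_length_bp, snps_per_chrom) for i in range(n_chromosomes)
    )
    blocks = []
    for chrom, length, _ in chroms:
        for s in np.linspace(0.08, 0.85, blocks_per_chrom) * length:
            blocks.append(
                PlantedBlock(
                    chrom,
                    int(s),
                    int(s) + int(rng.integers(150_000, 400_000)),
                    int(rng.integers(*block_snps)),
                    int(rng.integers(*founders)),
                )
            )
    return SimConfig(
        n_samples=n_samples, chromosomes=chroms, block_spec=tuple(blocks), seed=seed
    )


def graded_effects(n_snps: int) -> tuple[float, ...]:
    """Graded per-SNP betas (1.0, 1.2, ...); avoids degenerate cancellation
    between complementary founder haplotypes."""
    return tuple(1.0 + 0.2 * k for k in range(n_snps))


def truth_haploblocks(truth: GroundTruth):
    """Planted blocks as analysis Haploblock objects (panel indices)."""
    from .ld import Haploblock

    return [
        Haploblock(
            id=bid,
            chromosome=truth.block_bounds[bid][0],
            start_bp=truth.block_bounds[bid][1],
            end_bp=truth.block_bounds[bid][2],
            member_snps=tuple(truth.block_variants[bid]),
        )
        for bid in truth.block_variants
    ]


def write_trait_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index_label="sample", na_rep="NA")


def read_trait_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample", na_values="NA")
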