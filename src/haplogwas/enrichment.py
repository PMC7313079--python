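"""Haploblock set-enrichment over GWAS p-value rankings.

Each haploblock is treated as a set of SNPs; all panel SNPs are ranked
by increasing GWAS p-value and a GSEA-style weighted running sum is
walked down the ranking: hits (block members) increment by their rank
statistic (-log10 p, raised to ``alpha``) normalized over the block,
misses decrement by 1/(N - |block|). The enrichment score (ES) is the
running-sum value of maximal absolute deviation from zero. Significance
comes from a permutation null of random same-size SNP sets; only the
positive tail is tested because only positive ES (block members piled at
the significant end) is biologically meaningful, and BH FDR is applied
across blocks within each trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import GWASResult, bh_fdr
from .ld import Haploblock

MAX_NEGLOG10P = 300.0

ENRICHMENT_COLUMNS = ["trait", "block_id", "es", "p_perm", "q", "significant"]


@dataclass
class RankedSNPs:
    """Panel SNPs ordered by increasing GWAS p (most significant first)."""

    order: np.ndarray            # panel variant indices in rank order
    statistics: np.ndarray       # -log10(p_gc) in rank order, >= 0
    trait: str = "trait"

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order)
        self.statistics = np.asarray(self.statistics, dtype=float)
        if self.order.shape != self.statistics.shape:
            raise ValueError("order/statistics length mismatch")
        if (self.statistics < 0).any():
            raise ValueError("rank statistics must be non-negative")

    @property
    def n(self) -> int:
        return self.order.size

    def positions_of(self, members) -> np.ndarray:
        """0-based ranks of the given panel variant indices."""
        lookup = {int(v): r for r, v in enumerate(self.order)}
        try:
            return np.sort(np.array([lookup[int(m)] for m in members]))
        except KeyError as exc:
            raise KeyError(f"variant {exc} not present in the ranking") from exc


def filter_blocks(blocks: list[Haploblock], min_snps_exclusive: int = 6) -> list[Haploblock]:
    """Keep blocks with strictly more than ``min_snps_exclusive`` SNPs."""
    return [b for b in blocks if b.n_snps > min_snps_exclusive]


def rank_snps(gwas: GWASResult) -> RankedSNPs:
    """Rank the panel by increasing lambda-adjusted p, ties by coordinate.

    The variant-table row order is genomic (chromosome, position), so the
    stable positional tie-break is the table index.
    """
    p = gwas.table["p_gc"].to_numpy(dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("every SNP needs a finite p-value")
    pos = gwas.table["pos"].to_numpy()
    chrom_codes = np.unique(gwas.table["chrom"].to_numpy(), return_inverse=True)[1]
    order = np.lexsort((pos, chrom_codes, p))
    stats = np.minimum(-np.log10(p[order]), MAX_NEGLOG10P)
    return RankedSNPs(order, stats, trait=gwas.trait)


def _es_from_positions(P: np.ndarray, stats: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized GSEA running-sum extremum for sorted hit-rank matrix P.

    P has shape (B, k): each row the sorted 0-based hit ranks of one set.
    """
    N = stats.size
    B, k = P.shape
    if alpha == 0:
        S = np.ones_like(P, dtype=float)
    else:
        # scale out the maximum before powering: cancels in cum/tot and
        # keeps stat**alpha finite for any statistic magnitude
        scale = stats.max()
        S = (stats[P] / scale) ** alpha if scale > 0 else np.zeros(P.shape)
    tot = S.sum(axis=1)
    zero = tot <= 0
    if zero.any():  # all-zero statistics: fall back to unweighted steps
        S[zero] = 1.0
        tot[zero] = k
    cum = np.cumsum(S, axis=1) / tot[:, None]
    i = np.arange(1, k + 1)
    miss = 1.0 / (N - k)
    # after hit i the running sum is cum_i - (P_i + 1 - i) * miss;
    # just before hit i it is cum_{i-1} - (P_i - (i - 1)) * miss
    top = np.max(cum - (P + 1 - i) * miss, axis=1)
    cum_prev = np.concatenate([np.zeros((B, 1)), cum[:, :-1]], axis=1)
    bottom = np.min(cum_prev - (P - (i - 1)) * miss, axis=1)
    return np.where(top >= -bottom, top, bottom)  # ties resolve positive


def enrichment_score(ranked: RankedSNPs, block_members, alpha: float = 1.0) -> float:
    """ES of one SNP set over the ranking (signed max deviation)."""
    members = list(block_members)
    if len(members) == 0:
        raise ValueError("empty block")
    if len(members) >= ranked.n:
        raise ValueError("block must be a proper subset of the panel")
    P = ranked.positions_of(members)[None, :]
    return float(_es_from_positions(P, ranked.statistics, alpha)[0])


@dataclass
class EnrichmentResult:
    """Per-(block, trait) enrichment outcome."""

    block_id: str
    trait: str
    es: float
    p_perm: float
    q: float = field(default=np.nan)
    significant: bool = False


def permutation_test(
    ranked: RankedSNPs,
    blocks: list[Haploblock],
    n_perm: int = 100_000,
    seed: int = 0,
    alpha: float = 1.0,
    fdr: float = 0.05,
    chunk: int = 4000,
) -> pd.DataFrame:
    """Positive-tail permutation p-values for every block, plus BH FDR.

    The null draws random SNP sets of matched size without replacement
    from the panel. One permutation stream serves all block sizes: each
    permutation yields a random ordered sample of size max(|block|) whose
    prefixes are uniform random subsets of every smaller size.

    p_perm = (1 + #{null ES >= observed ES}) / (n_perm + 1); a block is
    significant when ES > 0 and its within-trait BH q < ``fdr``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if not blocks:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    N = ranked.n
    sizes = sorted({b.n_snps for b in blocks})
    if sizes[-1] >= N:
        raise ValueError("block larger than (or equal to) the panel")
    kmax = sizes[-1]

    obs = {
        b.id: enrichment_score(ranked, b.member_snps, alpha=alpha) for b in blocks
    }

    rng = np.random.default_rng(seed)
    exceed = {k: np.zeros(len([b for b in blocks if b.n_snps == k]), dtype=np.int64)
              for k in sizes}
    obs_by_size = {
        k: np.array([obs[b.id] for b in blocks if b.n_snps == k]) for k in sizes
    }
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        keys = rng.random((m, N))
        part = np.argpartition(keys, kmax - 1, axis=1)[:, :kmax]
        # order the sampled indices by key so every prefix is uniform
        sub_keys = np.take_along_axis(keys, part, axis=1)
        ordered = np.take_along_axis(part, np.argsort(sub_keys, axis=1), axis=1)
        for k in sizes:
            P = np.sort(ordered[:, :k], axis=1)
            null_es = _es_from_positions(P, ranked.statistics, alpha)
            exceed[k] += (null_es[:, None] >= obs_by_size[k][None, :]).sum(axis=0)
        done += m

    rows = []
    for k in sizes:
        ids = [b.id for b in blocks if b.n_snps == k]
        for bid, ex, es in zip(ids, exceed[k], obs_by_size[k]):
            rows.append((ranked.trait, bid, float(es),
                         (1.0 + ex) / (n_perm + 1.0)))
    df = pd.DataFrame(rows, columns=["trait", "block_id", "es", "p_perm"])
    df = df.set_index("block_id").loc[[b.id for b in blocks]].reset_index()
    df = df[["trait", "block_id", "es", "p_perm"]]
    df["q"] = bh_fdr(df["p_perm"].to_numpy())
    df["significant"] = (df["es"] > 0) & (df["q"] < fdr)
    return df


def enrich_all_traits(
    gwas_results: dict[str, GWASResult],
    blocks: list[Haploblock],
    n_perm: int = 100_000,
    seed: int = 0,
    alpha: float = 1.0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Run the permutation test per trait with per-trait child seeds."""
    frames = []
    seeds = np.random.SeedSequence(seed).spawn(len(gwas_results))
    for child, (name, gw) in zip(seeds, sorted(gwas_results.items())):
        ranked = rank_snps(gw)
        frames.append(
            permutation_test(ranked, blocks, n_perm=n_perm,
                             seed=int(child.generate_state(1)[0] % (2**31)),
                             alpha=alpha, fdr=fdr)
        )
    if not frames:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def enriched_sets_by_trait(results: pd.DataFrame) -> dict[str, set[str]]:
    """Map each trait to its set of significantly enriched block ids.

    Traits with no significant block map to the empty set.
    """
    out: dict[str, set[str]] = {t: set() for t in results["trait"].unique()}
    sig = results[results["significant"]]
    for t, bid in zip(sig["trait"], sig["block_id"]):
        out[t].add(bid)
    return out
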