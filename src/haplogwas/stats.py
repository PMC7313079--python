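"""Supporting descriptive statistics: Spearman matrices, nucleotide
diversity over polymorphic sites, and Mann-Whitney group comparisons."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class CorrelationMatrix:
    labels: list[str]
    r: pd.DataFrame = field(repr=False)
    n_pairs: pd.DataFrame = field(repr=False)


def spearman_matrix(table: pd.DataFrame, min_pairs: int = 3) -> CorrelationMatrix:
    """Pairwise-complete Spearman correlations with average ranks for ties.

    Entries with fewer than ``min_pairs`` complete pairs, or involving a
    constant column, are reported as NaN.
    """
    labels = list(table.columns)
    m = len(labels)
    R = np.full((m, m), np.nan)
    N = np.zeros((m, m), dtype=int)
    vals = table.to_numpy(dtype=float)
    for i in range(m):
        R[i, i] = 1.0
        N[i, i] = int(np.isfinite(vals[:, i]).sum())
        for j in range(i + 1, m):
            ok = np.isfinite(vals[:, i]) & np.isfinite(vals[:, j])
            N[i, j] = N[j, i] = int(ok.sum())
            if ok.sum() < min_pairs:
                continue
            x, y = vals[ok, i], vals[ok, j]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue  # constant column: undefined, left NaN
            R[i, j] = R[j, i] = sps.spearmanr(x, y).statistic
    return CorrelationMatrix(
        labels,
        pd.DataFrame(R, index=labels, columns=labels),
        pd.DataFrame(N, index=labels, columns=labels),
    )


def site_pi(gm, groups) -> pd.DataFrame:
    """Mean per-site nucleotide diversity over polymorphic sites.

    Within each (geographic group, chromosome): per site,
    pi = (n/(n-1)) * 2 p (1-p) with n the non-missing allele count and p
    the alt-allele frequency; sites monomorphic within the group are
    excluded from that group's mean (which overestimates genome-wide
    diversity but supports between-group comparison). Invariant to
    ref/alt relabeling since 2p(1-p) is symmetric in p.
    """
    groups = np.asarray(groups)
    if groups.shape[0] != gm.n_samples:
        raise ValueError("groups length does not match sample count")
    rows = []
    for g in pd.unique(groups):
        sel = groups == g
        d = gm.dosages[sel]
        n_geno = np.sum(~np.isnan(d), axis=0)
        if (n_geno >= 2).sum() == 0:
            raise ValueError(f"group {g!r} has <2 genotyped samples at every site")
        with np.errstate(invalid="ignore", divide="ignore"):
            n_alleles = 2.0 * n_geno
            p = np.nansum(d, axis=0) / n_alleles
            pi = (n_alleles / (n_alleles - 1.0)) * 2.0 * p * (1.0 - p)
        poly = (n_geno >= 2) & (p > 0) & (p < 1)
        for chrom in gm.chromosomes:
            on_chrom = (gm.variants["chrom"] == chrom).to_numpy()
            use = poly & on_chrom
            rows.append(
                (g, chrom, float(np.mean(pi[use])) if use.any() else np.nan,
                 int(use.sum()))
            )
    return pd.DataFrame(rows, columns=["group", "chrom", "pi", "n_polymorphic_sites"])


def site_pi_value(p: float, n_alleles: int) -> float:
    """Single-site pi = (n/(n-1)) * 2 p (1-p)."""
    return (n_alleles / (n_alleles - 1.0)) * 2.0 * p * (1.0 - p)


def mann_whitney_groups(values, groups, exact_max_n: int = 20) -> pd.DataFrame:
    """Two-sided Mann-Whitney U for every group pair.

    Exact enumeration when both groups are <= ``exact_max_n`` and the
    pooled values are tie-free; otherwise the normal approximation with
    tie correction.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            xa = values[groups == a]
            xb = values[groups == b]
            if xa.size < 2 or xb.size < 2:
                raise ValueError("each group needs at least 2 samples")
            pooled = np.concatenate([xa, xb])
            ties = np.unique(pooled).size < pooled.size
            method = (
                "exact"
                if (xa.size <= exact_max_n and xb.size <= exact_max_n and not ties)
                else "asymptotic"
            )
            res = sps.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
            rows.append((a, b, xa.size, xb.size, float(res.statistic),
                         float(res.pvalue), method))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "n_a", "n_b", "U", "p", "method"]
    )
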