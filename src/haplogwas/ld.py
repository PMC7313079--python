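"""Linkage disequilibrium structure and haploblock partitioning.

r-squared is computed between genotype dosage columns (composite LD);
in a highly selfed panel this is close to haplotype r2. The unlinked
(cross-chromosome) r2 distribution calibrates a critical value — by
default its parametric 95th percentile — below which intra-chromosomal
LD is indistinguishable from background; the distance at which a
second-degree LOESS of r2 against physical distance first drops to that
critical value estimates the LD decay range.

Blocks follow the confidence-interval method of Gabriel et al. as used
by Haploview: pairwise |D'| likelihoods on a grid give a CI per pair,
pairs are classified strong-LD / recombination / uninformative with the
default CI thresholds [0.7, 0.98], and maximal marker runs whose pairs
are overwhelmingly strong-LD become blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

MIN_PAIR_SAMPLES = 20

PAIR_COLUMNS = ["i", "j", "same_chromosome", "distance_bp", "r2", "n_used"]


@dataclass(frozen=True)
class DPrimeCI:
    """|D'| point estimate with a likelihood-based confidence interval."""

    dprime: float
    ci_low: float
    ci_high: float
    klass: str  # strong_ld | recombination | uninformative


@dataclass(frozen=True)
class Haploblock:
    """A contiguous run of markers in strong mutual LD."""

    id: str
    chromosome: str
    start_bp: int
    end_bp: int
    member_snps: tuple[int, ...]  # panel variant indices, contiguous

    @property
    def n_snps(self) -> int:
        return len(self.member_snps)


def _pair_r2_chunk(X: np.ndarray, ii: np.ndarray, jj: np.ndarray,
                   min_samples: int = MIN_PAIR_SAMPLES):
    """Pairwise-complete squared Pearson r for column index pairs."""
    xi, xj = X[:, ii], X[:, jj]
    ok = ~(np.isnan(xi) | np.isnan(xj))
    n = ok.sum(axis=0).astype(float)
    xi0 = np.where(ok, xi, 0.0)
    xj0 = np.where(ok, xj, 0.0)
    sx = xi0.sum(0)
    sy = xj0.sum(0)
    sxx = (xi0 * xi0).sum(0)
    syy = (xj0 * xj0).sum(0)
    sxy = (xi0 * xj0).sum(0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r2 = (cov * cov) / (varx * vary)
    bad = (n < min_samples) | (varx <= 0) | (vary <= 0)
    r2[bad] = np.nan
    return r2, n.astype(int)


def pairwise_r2(
    gm,
    scope: str = "intra_chromosomal",
    max_pairs: int = 100_000,
    seed: int = 0,
    chunk: int = 20_000,
    min_samples: int = MIN_PAIR_SAMPLES,
) -> pd.DataFrame:
    """Pairwise dosage r2, either same-chromosome or unlinked pairs.

    Unlinked pairs (different chromosomes) are subsampled to ``max_pairs``
    with the given seed; intra-chromosomal pairs are likewise subsampled
    if they exceed ``max_pairs``. Pairs with fewer than 20 pairwise-
    complete samples or a monomorphic column are dropped.
    """
    if gm.n_variants < 2:
        raise ValueError("need at least two variants")
    chrom = gm.variants["chrom"].to_numpy()
    pos = gm.variants["pos"].to_numpy()
    rng = np.random.default_rng(seed)

    if scope == "intra_chromosomal":
        ii_list, jj_list = [], []
        for c in gm.chromosomes:
            idx = gm.chromosome_indices(c)
            if idx.size < 2:
                continue
            a, b = np.triu_indices(idx.size, k=1)
            ii_list.append(idx[a])
            jj_list.append(idx[b])
        if not ii_list:
            raise ValueError("no same-chromosome pairs available")
        ii = np.concatenate(ii_list)
        jj = np.concatenate(jj_list)
        if ii.size > max_pairs:
            take = rng.choice(ii.size, size=max_pairs, replace=False)
            ii, jj = ii[take], jj[take]
    elif scope == "unlinked":
        if len(gm.chromosomes) < 2:
            raise ValueError("unlinked scope requires at least two chromosomes")
        want = max_pairs
        pairs: set[tuple[int, int]] = set()
        while len(pairs) < want:
            cand = rng.integers(0, gm.n_variants, size=(2 * (want - len(pairs)) + 16, 2))
            for a, b in cand:
                if chrom[a] == chrom[b]:
                    continue
                key = (int(a), int(b)) if a < b else (int(b), int(a))
                pairs.add(key)
                if len(pairs) == want:
                    break
            # all cross-chromosome pairs exhausted?
            n_cross = sum(
                gm.chromosome_indices(c1).size * gm.chromosome_indices(c2).size
                for k, c1 in enumerate(gm.chromosomes)
                for c2 in gm.chromosomes[k + 1:]
            )
            if len(pairs) >= n_cross:
                break
        arr = np.array(sorted(pairs))
        ii, jj = arr[:, 0], arr[:, 1]
    else:
        raise ValueError(f"unknown scope {scope!r}")

    recs = []
    for s in range(0, ii.size, chunk):
        a = ii[s : s + chunk]
        b = jj[s : s + chunk]
        r2, n = _pair_r2_chunk(gm.dosages, a, b, min_samples)
        same = chrom[a] == chrom[b]
        dist = np.where(same, np.abs(pos[a] - pos[b]), -1)
        recs.append(
            pd.DataFrame(
                {"i": a, "j": b, "same_chromosome": same, "distance_bp": dist,
                 "r2": r2, "n_used": n}
            )
        )
    out = pd.concat(recs, ignore_index=True)
    out = out[np.isfinite(out["r2"])].reset_index(drop=True)
    return out


def unlinked_critical_r2(
    unlinked: pd.DataFrame | np.ndarray,
    percentile: float = 0.95,
    mode: str = "parametric_normal",
) -> float:
    """Critical r2 from the unlinked distribution.

    parametric_normal: mean + z(percentile) * sd; empirical: the sample
    quantile. The parametric 95th percentile is the study default.
    """
    r2 = np.asarray(unlinked["r2"] if isinstance(unlinked, pd.DataFrame) else unlinked,
                    dtype=float)
    r2 = r2[np.isfinite(r2)]
    if r2.size == 0:
        raise ValueError("no unlinked r2 values")
    if mode == "parametric_normal":
        return float(r2.mean() + sps.norm.ppf(percentile) * r2.std(ddof=1))
    if mode == "empirical":
        return float(np.quantile(r2, percentile))
    raise ValueError(f"unknown mode {mode!r}")


def _loess2(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray, span: float) -> np.ndarray:
    """Tricube-weighted local quadratic regression (degree-2 LOESS)."""
    n = x.size
    q = max(int(np.ceil(span * n)), 6)
    q = min(q, n)
    fitted = np.empty(x_eval.size)
    for k, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        h = np.partition(d, q - 1)[q - 1]
        if h <= 0:
            h = max(d.max(), 1.0)
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        use = w > 0
        xs = x[use] - x0
        ws = w[use]
        ys = y[use]
        # weighted quadratic via normal equations on centered x
        X = np.column_stack([np.ones(xs.size), xs, xs * xs])
        WX = X * ws[:, None]
        A = X.T @ WX
        b = WX.T @ ys
        try:
            coef = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            coef = np.linalg.lstsq(X * np.sqrt(ws)[:, None],
                                   ys * np.sqrt(ws), rcond=None)[0]
        fitted[k] = coef[0]
    return fitted


@dataclass
class LDDecayFit:
    """LOESS LD-decay curve and its crossing of the critical r2."""

    distances: np.ndarray
    fitted_r2: np.ndarray
    critical_r2: float
    decay_range_bp: float | None  # None: curve never reaches the threshold

    @property
    def curve(self) -> pd.DataFrame:
        return pd.DataFrame({"distance_bp": self.distances, "r2": self.fitted_r2})


def fit_ld_decay(
    intra: pd.DataFrame,
    critical_r2: float,
    loess_span: float = 0.3,
    n_eval: int = 200,
) -> LDDecayFit:
    """Fit the degree-2 LOESS decay curve and locate the threshold crossing.

    decay_range_bp is the smallest distance at which the fitted curve
    first drops to <= critical_r2 (linear interpolation between
    evaluation points); None if it never crosses.
    """
    x = intra["distance_bp"].to_numpy(dtype=float)
    y = intra["r2"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & (x >= 0)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.unique(x).size < 2:
        raise ValueError("need intra-chromosomal pairs spanning >1 distance")
    x_eval = np.linspace(x.min(), x.max(), n_eval)
    fitted = _loess2(x, y, x_eval, loess_span)

    decay: float | None = None
    below = fitted <= critical_r2
    if below[0]:
        decay = float(x_eval[0])
    else:
        idx = np.flatnonzero(below)
        if idx.size:
            k = idx[0]
            x0, x1 = x_eval[k - 1], x_eval[k]
            y0, y1 = fitted[k - 1], fitted[k]
            decay = float(x0 + (y0 - critical_r2) / (y0 - y1) * (x1 - x0))
    return LDDecayFit(x_eval, fitted, float(critical_r2), decay)


# ---------------------------------------------------------------------------
# |D'| confidence intervals and block partitioning
# ---------------------------------------------------------------------------

def _genotype_counts(X: np.ndarray, i: int, j: int) -> np.ndarray:
    xi, xj = X[:, i], X[:, j]
    ok = ~(np.isnan(xi) | np.isnan(xj))
    a = xi[ok].astype(int)
    b = xj[ok].astype(int)
    return np.bincount(3 * a + b, minlength=9).reshape(3, 3)


def _em_haplotype_freqs(counts: np.ndarray, tol: float = 1e-10, max_iter: int = 1000):
    """EM haplotype frequencies (AB, Ab, aB, ab) from 3x3 genotype counts.

    A/B denote the alt alleles. Only the double-heterozygote cell is
    phase-ambiguous; everything else contributes fixed haplotype counts.
    """
    n = counts.sum()
    if n == 0:
        raise ValueError("no complete samples")
    # fixed haplotype counts from unambiguous cells: genotype (i, j) in
    # dosage space contributes haplotypes deterministically unless i==j==1
    fixed = np.zeros(4)  # AB, Ab, aB, ab
    for gi in range(3):
        for gj in range(3):
            if gi == 1 and gj == 1:
                continue
            c = counts[gi, gj]
            if c == 0:
                continue
            a_alleles = [1] * gi + [0] * (2 - gi)
            b_alleles = [1] * gj + [0] * (2 - gj)
            if gi == 1:
                pairs = [(1, b_alleles[0]), (0, b_alleles[1])]
            elif gj == 1:
                pairs = [(a_alleles[0], 1), (a_alleles[1], 0)]
            else:
                pairs = [(a_alleles[0], b_alleles[0]), (a_alleles[1], b_alleles[1])]
            for aa, bb in pairs:
                fixed[(1 - aa) * 2 + (1 - bb)] += c
    ndh = counts[1, 1]  # double hets: AB/ab or Ab/aB
    f = np.full(4, 0.25)
    ll_old = -np.inf
    for _ in range(max_iter):
        denom = f[0] * f[3] + f[1] * f[2]
        frac = 0.5 if denom <= 0 else (f[0] * f[3]) / denom
        h = fixed.copy()
        h[0] += ndh * frac
        h[3] += ndh * frac
        h[1] += ndh * (1 - frac)
        h[2] += ndh * (1 - frac)
        f_new = h / h.sum()
        ll = _pair_loglik(counts, f_new)
        f = f_new
        if ll - ll_old < tol * max(abs(ll), 1.0) and ll >= ll_old:
            break
        ll_old = ll
    return f


_HAP_DOSE = np.array([(1, 1), (1, 0), (0, 1), (0, 0)])  # alt-allele dose of AB,Ab,aB,ab


def _cell_probs(f: np.ndarray) -> np.ndarray:
    """3x3 genotype cell probabilities under HWE from haplotype freqs.

    ``f`` may be (4,) or (G, 4) for a grid of frequency vectors.
    """
    f = np.atleast_2d(f)
    P = np.zeros((f.shape[0], 3, 3))
    for h1 in range(4):
        for h2 in range(4):
            gi = _HAP_DOSE[h1, 0] + _HAP_DOSE[h2, 0]
            gj = _HAP_DOSE[h1, 1] + _HAP_DOSE[h2, 1]
            P[:, gi, gj] += f[:, h1] * f[:, h2]
    return P


def _pair_loglik(counts: np.ndarray, f: np.ndarray) -> float:
    P = _cell_probs(f)[0]
    with np.errstate(divide="ignore"):
        lp = np.log(P)
    lp[P <= 0] = -1e30
    return float((counts * lp).sum())


def dprime_ci_from_counts(
    counts: np.ndarray, grid_step: float = 0.001, ci_mass: float = 0.90
) -> DPrimeCI:
    """Haploview-style likelihood CI for |D'| from a 3x3 genotype table."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    pA = (2 * counts[2, :].sum() + counts[1, :].sum()) / (2 * n)
    pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic variant in pair")

    f = _em_haplotype_freqs(counts)
    D = f[0] - pA * pB
    if D < 0:  # relabel locus-B alleles so D >= 0; |D'| is invariant
        counts = counts[:, ::-1]
        pB = 1.0 - pB
        D = -D
    dmax = min(pA * (1 - pB), (1 - pA) * pB)
    if dmax <= 0:
        raise ValueError("degenerate allele frequencies")
    dprime = min(D / dmax, 1.0)

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    Dg = grid * dmax
    fg = np.column_stack([
        pA * pB + Dg,
        pA * (1 - pB) - Dg,
        (1 - pA) * pB - Dg,
        (1 - pA) * (1 - pB) + Dg,
    ])
    fg = np.clip(fg, 0.0, 1.0)
    P = _cell_probs(fg)
    with np.errstate(divide="ignore"):
        lp = np.log(P)
    lp[P <= 0] = -1e30
    ll = np.einsum("gij,ij->g", lp, counts)
    ll -= ll.max()
    post = np.exp(ll)
    post /= post.sum()
    # Haploview convention: accumulate (1-mass)/2 of posterior mass inward
    # from each end; the crossing bins are the CI bounds
    lo_q = (1.0 - ci_mass) / 2.0
    cum = np.cumsum(post)
    tail_high = np.cumsum(post[::-1])[::-1]  # mass at or above each grid point
    ci_low = float(grid[np.searchsorted(cum, lo_q)])
    ci_high = float(grid[np.flatnonzero(tail_high >= lo_q)[-1]])
    ci_low, ci_high = min(ci_low, ci_high), max(ci_low, ci_high)
    # keep the EM point estimate inside (can differ by < one grid step)
    ci_low = min(ci_low, dprime)
    ci_high = max(ci_high, dprime)

    if ci_low >= 0.70 and ci_high >= 0.98:
        klass = "strong_ld"
    elif ci_high < 0.90:
        klass = "recombination"
    else:
        klass = "uninformative"
    return DPrimeCI(float(dprime), ci_low, ci_high, klass)


def dprime_ci(gm, i: int, j: int, grid_step: float = 0.001,
              ci_mass: float = 0.90) -> DPrimeCI:
    """|D'| CI between two panel variants (EM over unphased genotypes)."""
    counts = _genotype_counts(gm.dosages, i, j)
    if counts.sum() < MIN_PAIR_SAMPLES:
        raise ValueError("fewer than 20 pairwise-complete samples")
    return dprime_ci_from_counts(counts, grid_step=grid_step, ci_mass=ci_mass)


def _pair_class(gm, i: int, j: int, grid_step: float, ci_mass: float,
                min_pair_maf: float) -> str:
    counts = _genotype_counts(gm.dosages, i, j)
    n = counts.sum()
    if n < MIN_PAIR_SAMPLES:
        return "uninformative"
    pA = (2 * counts[2, :].sum() + counts[1, :].sum()) / (2 * n)
    pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)
    if min(pA, 1 - pA) < min_pair_maf or min(pB, 1 - pB) < min_pair_maf:
        return "uninformative"
    try:
        return dprime_ci_from_counts(counts, grid_step, ci_mass).klass
    except ValueError:
        return "uninformative"


def partition_haploblocks(
    gm,
    max_block_span_bp: int = 500_000,
    informative_fraction: float = 0.95,
    grid_step: float = 0.001,
    ci_mass: float = 0.90,
    min_pair_maf: float = 0.0,
) -> list[Haploblock]:
    """Gabriel-CI haploblock partition of the panel.

    A candidate block is a contiguous marker run (span <= max span) whose
    outermost pair is strong-LD and whose informative pairs are at least
    ``informative_fraction`` strong-LD among strong-LD + recombination.
    Candidates are accepted greedily by descending marker count (ties:
    longer bp span, then leftmost), discarding overlaps.
    """
    blocks: list[Haploblock] = []
    for chrom in gm.chromosomes:
        idx = gm.chromosome_indices(chrom)
        pos = gm.variants["pos"].to_numpy()[idx]
        m = idx.size
        if m < 2:
            continue
        cache: dict[tuple[int, int], str] = {}

        def klass(a: int, b: int) -> str:
            key = (a, b)
            if key not in cache:
                cache[key] = _pair_class(gm, int(idx[a]), int(idx[b]),
                                         grid_step, ci_mass, min_pair_maf)
            return cache[key]

        candidates = []
        for a in range(m - 1):
            for b in range(a + 1, m):
                if pos[b] - pos[a] > max_block_span_bp:
                    break
                if klass(a, b) != "strong_ld":
                    continue
                n_strong = n_recomb = 0
                for u in range(a, b):
                    for v in range(u + 1, b + 1):
                        k = klass(u, v)
                        if k == "strong_ld":
                            n_strong += 1
                        elif k == "recombination":
                            n_recomb += 1
                informative = n_strong + n_recomb
                if informative == 0:
                    continue
                if n_strong / informative >= informative_fraction:
                    candidates.append((b - a + 1, int(pos[b] - pos[a]), a, b))

        candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
        used = np.zeros(m, dtype=bool)
        accepted = []
        for _cnt, _span, a, b in candidates:
            if used[a : b + 1].any():
                continue
            used[a : b + 1] = True
            accepted.append((a, b))
        accepted.sort()
        for k, (a, b) in enumerate(accepted, start=1):
            blocks.append(
                Haploblock(
                    id=f"{chrom}_block{k}",
                    chromosome=chrom,
                    start_bp=int(pos[a]),
                    end_bp=int(pos[b]),
                    member_snps=tuple(int(v) for v in idx[a : b + 1]),
                )
            )
    return blocks


def blocks_to_table(blocks: list[Haploblock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (b.id, b.chromosome, b.start_bp, b.end_bp, b.n_snps,
             ",".join(map(str, b.member_snps)))
            for b in blocks
        ],
        columns=["block_id", "chrom", "start_bp", "end_bp", "n_snps", "member_snps"],
    )


def write_blocks_text(blocks: list[Haploblock], path: str) -> None:
    blocks_to_table(blocks).to_csv(path, sep="\t", index=False)


def write_blocks_bed(blocks: list[Haploblock], path: str) -> None:
    """BED (0-based half-open) from the internal 1-based closed intervals."""
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chromosome}\t{b.start_bp - 1}\t{b.end_bp}\t{b.id}\n")


def read_blocks_text(path: str) -> list[Haploblock]:
    df = pd.read_csv(path, sep="\t")
    return [
        Haploblock(
            id=r.block_id, chromosome=r.chrom, start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
            member_snps=tuple(int(x) for x in str(r.member_snps).split(",")),
        )
        for r in df.itertuples(index=False)
    ]
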