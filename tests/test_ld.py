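import numpy as np
import pytest

from haplogwas import ld
from haplogwas.simulate import PlantedBlock, SimConfig, simulate_genotypes

from conftest import make_gm


# ---------------------------------------------------------------- pairwise r2

def test_r2_matches_brute_force_pearson():
    a = np.array([2, 2, 0, 0, 2, 0, 1, 1], dtype=float)
    b = np.array([2, 0, 0, 2, 2, 0, 1, 1], dtype=float)
    gm = make_gm(np.column_stack([a, b]))
    pairs = ld.pairwise_r2(gm, "intra_chromosomal", min_samples=4)
    expected = np.corrcoef(a, b)[0, 1] ** 2  # independent oracle
    np.testing.assert_allclose(pairs["r2"].iloc[0], expected, rtol=1e-12)
    assert pairs["n_used"].iloc[0] == 8


def test_r2_identical_and_orthogonal_columns():
    a = np.array([0, 1, 2, 0, 1, 2, 0, 1] * 3, dtype=float)
    # zero sample covariance with a by construction
    b = np.array([0, 0, 0, 2, 2, 2, 1, 1] * 3, dtype=float)
    assert abs(np.cov(a, b)[0, 1]) < 1e-12
    gm = make_gm(np.column_stack([a, a.copy(), b]))
    pairs = ld.pairwise_r2(gm, "intra_chromosomal").set_index(["i", "j"])
    np.testing.assert_allclose(pairs.loc[(0, 1), "r2"], 1.0)
    np.testing.assert_allclose(pairs.loc[(0, 2), "r2"], 0.0, atol=1e-12)


def test_r2_invariant_to_allele_relabeling():
    rng = np.random.default_rng(1)
    d = rng.integers(0, 3, size=(60, 2)).astype(float)
    gm = make_gm(d)
    flipped = d.copy()
    flipped[:, 1] = 2 - flipped[:, 1]  # swap ref/alt of second variant
    gm2 = make_gm(flipped)
    r1 = ld.pairwise_r2(gm, "intra_chromosomal")["r2"].iloc[0]
    r2 = ld.pairwise_r2(gm2, "intra_chromosomal")["r2"].iloc[0]
    np.testing.assert_allclose(r1, r2, rtol=1e-12)


def test_r2_drops_low_count_and_monomorphic_pairs():
    d = np.ones((30, 3))
    d[:15, 0] = 0.0
    d[:15, 1] = 0.0
    d[10:, 1] = np.nan  # only 10 complete pairs with others
    # column 2 monomorphic
    gm = make_gm(d)
    pairs = ld.pairwise_r2(gm, "intra_chromosomal")
    assert set(zip(pairs["i"], pairs["j"])) == set()  # all pairs dropped


def test_unlinked_scope_requires_two_chromosomes():
    gm = make_gm(np.random.default_rng(0).integers(0, 3, (40, 4)).astype(float))
    with pytest.raises(ValueError, match="two chromosomes"):
        ld.pairwise_r2(gm, "unlinked")


def test_unlinked_pairs_cross_chromosomes(two_block_panel):
    gm, _ = two_block_panel
    pairs = ld.pairwise_r2(gm, "unlinked", max_pairs=200, seed=3)
    chrom = gm.variants["chrom"].to_numpy()
    assert len(pairs) > 0
    assert (~pairs["same_chromosome"]).all()
    assert (chrom[pairs["i"]] != chrom[pairs["j"]]).all()


# ------------------------------------------------------------ critical value

def test_critical_r2_constant_input_both_modes():
    r2 = np.full(200, 0.07)
    for mode in ("parametric_normal", "empirical"):
        np.testing.assert_allclose(
            ld.unlinked_critical_r2(r2, mode=mode), 0.07, atol=1e-12
        )


def test_critical_r2_parametric_matches_direct_formula():
    rng = np.random.default_rng(5)
    r2 = rng.beta(0.5, 8.0, size=10_000)
    got = ld.unlinked_critical_r2(r2, percentile=0.95)
    expected = r2.mean() + 1.6448536269514722 * r2.std(ddof=1)
    np.testing.assert_allclose(got, expected, rtol=1e-9)


def test_critical_r2_empty_errors():
    with pytest.raises(ValueError):
        ld.unlinked_critical_r2(np.array([]))


# ------------------------------------------------------------------ LD decay

def _exp_decay_pairs(d0=500_000.0, n=4000, noise=0.02, seed=0):
    import pandas as pd

    rng = np.random.default_rng(seed)
    d = rng.uniform(0, 3_000_000, size=n)
    r2 = np.clip(0.8 * np.exp(-d / d0) + rng.normal(0, noise, size=n), 0, 1)
    return pd.DataFrame({"distance_bp": d, "r2": r2})


def test_ld_decay_crossing_matches_analytic():
    pairs = _exp_decay_pairs()
    fit = ld.fit_ld_decay(pairs, critical_r2=0.16, loess_span=0.25)
    analytic = 500_000.0 * np.log(0.8 / 0.16)
    assert fit.decay_range_bp is not None
    assert abs(fit.decay_range_bp - analytic) / analytic < 0.10
    assert fit.critical_r2 == 0.16


def test_ld_decay_never_crossing_flagged():
    pairs = _exp_decay_pairs()
    fit = ld.fit_ld_decay(pairs, critical_r2=1e-6, loess_span=0.25)
    assert fit.decay_range_bp is None


def test_ld_decay_single_distance_errors():
    import pandas as pd

    pairs = pd.DataFrame({"distance_bp": [100.0] * 60, "r2": np.linspace(0, 1, 60)})
    with pytest.raises(ValueError, match="distance"):
        ld.fit_ld_decay(pairs, critical_r2=0.16)


# ------------------------------------------------------------- D' CI classes

def test_perfect_ld_gives_dprime_one_strong_class():
    d = np.zeros((50, 2))
    d[25:, :] = 2.0  # all samples (0,0) or (2,2)
    gm = make_gm(d)
    ci = ld.dprime_ci(gm, 0, 1)
    np.testing.assert_allclose(ci.dprime, 1.0, atol=1e-9)
    assert ci.klass == "strong_ld"
    assert ci.ci_low <= ci.dprime <= ci.ci_high


def test_independent_loci_classified_recombination():
    rng = np.random.default_rng(7)
    hits = 0
    n_rep = 11
    for _ in range(n_rep):
        # two independent loci, allele freq 0.5, n=500, HWE genotypes
        g = rng.binomial(1, 0.5, size=(500, 2, 2)).sum(axis=2).astype(float)
        gm = make_gm(g)
        ci = ld.dprime_ci(gm, 0, 1)
        if ci.klass == "recombination":
            hits += 1
        assert ci.ci_low <= ci.ci_high
    assert hits > n_rep / 2


def test_dprime_invariant_to_allele_relabeling():
    rng = np.random.default_rng(3)
    d = rng.integers(0, 3, size=(200, 2)).astype(float)
    gm = make_gm(d)
    flipped = d.copy()
    flipped[:, 0] = 2 - flipped[:, 0]
    gm2 = make_gm(flipped)
    c1 = ld.dprime_ci(gm, 0, 1)
    c2 = ld.dprime_ci(gm2, 0, 1)
    np.testing.assert_allclose(c1.dprime, c2.dprime, atol=1e-6)
    np.testing.assert_allclose(c1.ci_low, c2.ci_low, atol=1e-3)
    np.testing.assert_allclose(c1.ci_high, c2.ci_high, atol=1e-3)


def test_dprime_monomorphic_errors():
    d = np.column_stack([np.zeros(40), np.tile([0.0, 2.0], 20)])
    gm = make_gm(d)
    with pytest.raises(ValueError, match="monomorphic"):
        ld.dprime_ci(gm, 0, 1)


# --------------------------------------------------------------- haploblocks

def _filtered_map(gm_raw, gm_filt):
    key = {
        (r.chrom, r.pos): i
        for i, r in enumerate(gm_filt.variants.itertuples(index=False))
    }
    return {
        bid: i for (bid, i) in key.items()
    }, key


def test_partition_recovers_planted_blocks(two_block_panel):
    from haplogwas.genio import filter_variants

    gm_raw, truth = two_block_panel
    gm = filter_variants(gm_raw)
    key = {
        (r.chrom, r.pos): i
        for i, r in enumerate(gm.variants.itertuples(index=False))
    }
    raw_var = gm_raw.variants
    blocks = ld.partition_haploblocks(gm, max_block_span_bp=500_000)
    found = {frozenset(b.member_snps) for b in blocks}
    for bid, idxs in truth.block_variants.items():
        planted = frozenset(
            key[(raw_var["chrom"][i], raw_var["pos"][i])]
            for i in idxs
            if (raw_var["chrom"][i], raw_var["pos"][i]) in key
        )
        assert planted in found, f"{bid} not recovered exactly"


def test_partition_blocks_contiguous_nonoverlapping(two_block_panel):
    from haplogwas.genio import filter_variants

    gm = filter_variants(two_block_panel[0])
    blocks = ld.partition_haploblocks(gm)
    seen = set()
    for b in blocks:
        members = list(b.member_snps)
        assert members == list(range(members[0], members[-1] + 1))
        assert not seen & set(members)
        seen.update(members)
        assert b.start_bp <= b.end_bp


def test_partition_single_snp_chromosome_empty():
    gm = make_gm(np.tile([0.0, 2.0], 20)[:, None])
    assert ld.partition_haploblocks(gm) == []


def test_partition_invariant_to_sample_order(two_block_panel):
    from haplogwas.genio import GenotypeMatrix, filter_variants

    gm = filter_variants(two_block_panel[0])
    rng = np.random.default_rng(0)
    perm = rng.permutation(gm.n_samples)
    gm_perm = GenotypeMatrix(
        gm.dosages[perm], [gm.sample_ids[i] for i in perm], gm.variants.copy()
    )
    b1 = ld.partition_haploblocks(gm)
    b2 = ld.partition_haploblocks(gm_perm)
    assert [b.member_snps for b in b1] == [b.member_snps for b in b2]


def test_blocks_text_and_bed_round_trip(tmp_path, two_block_panel):
    from haplogwas.genio import filter_variants

    gm = filter_variants(two_block_panel[0])
    blocks = ld.partition_haploblocks(gm)
    assert blocks
    path = tmp_path / "blocks.tsv"
    ld.write_blocks_text(blocks, path)
    back = ld.read_blocks_text(path)
    assert [b.member_snps for b in back] == [b.member_snps for b in blocks]
    bed = tmp_path / "blocks.bed"
    ld.write_blocks_bed(blocks, bed)
    line = bed.read_text().splitlines()[0].split("\t")
    assert int(line[1]) == blocks[0].start_bp - 1
    assert int(line[2]) == blocks[0].end_bp
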