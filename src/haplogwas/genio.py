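"""Genotype matrix container, VCF input/output and marker filtering.

The panel is held as a samples x variants matrix of alt-allele dosages
(0, 1, 2, with ``nan`` for missing calls), plus a variant table with
1-based VCF coordinates. Only biallelic SNPs are kept; multi-allelic or
indel records are skipped on read with a warning rather than split,
because splitting introduces dosage ambiguity for a selfing diploid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP dosage matrix with variant coordinates.

    Attributes
    ----------
    dosages : float ndarray, shape (n_samples, n_variants)
        Alt-allele counts in {0, 1, 2}; missing genotypes are ``nan``.
    sample_ids : list of str
    variants : DataFrame with columns chrom, pos (1-based), ref, alt.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    variants: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match dosage rows")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant table length does not match dosage columns")
        self.variants = self.variants.reset_index(drop=True)
        pos = self.variants["pos"].to_numpy()
        chrom = self.variants["chrom"].to_numpy()
        same = chrom[1:] == chrom[:-1] if len(chrom) > 1 else np.array([], bool)
        if np.any(pos[1:][same] <= pos[:-1][same]):
            raise ValueError("positions must be strictly increasing within a chromosome")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.variants["chrom"]))

    def chromosome_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.variants["chrom"] == chrom).to_numpy())

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing genotypes."""
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def maf(self) -> np.ndarray:
        """Per-variant minor allele frequency over non-missing alleles."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, idx],
            list(self.sample_ids),
            self.variants.iloc[np.asarray(idx)].reset_index(drop=True),
        )


@dataclass(frozen=True)
class VariantFilterSpec:
    """Marker-retention thresholds: call rate and minor allele frequency.

    Defaults match the standard landrace-panel filter: markers present in
    at least 90% of genotypes with MAF of at least 3%.
    """

    min_call_rate: float = 0.90
    min_maf: float = 0.03

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF with GT fields into a :class:`GenotypeMatrix`.

    Dosage is the alt-allele count; ``./.`` becomes ``nan``. Multi-allelic
    or non-SNP records are skipped with a logged warning.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    rows: list[tuple] = []
    n_skipped = 0
    for rec in vcf:
        alts = rec.ALT
        if (
            len(alts) != 1
            or len(rec.REF) != 1
            or len(alts[0]) != 1
            or rec.REF.upper() not in _BASES
            or alts[0].upper() not in _BASES
        ):
            n_skipped += 1
            logger.warning(
                "skipping non-biallelic-SNP record %s:%d %s>%s",
                rec.CHROM, rec.POS, rec.REF, ",".join(alts) or ".",
            )
            continue
        # gts012: 0/1/2 dosage, 3 = unknown
        d = rec.gt_types.astype(float)
        d[d == 3] = np.nan
        cols.append(d)
        rows.append((rec.CHROM, rec.POS, rec.REF.upper(), alts[0].upper()))
    vcf.close()
    if not cols:
        raise ValueError(f"no biallelic SNP records in {path}")
    if n_skipped:
        logger.warning("skipped %d non-biallelic-SNP records", n_skipped)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return GenotypeMatrix(np.column_stack(cols), samples, variants)


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write dosages as a minimal VCF 4.2 with GT fields (``./.`` missing)."""
    chrom_lengths = gm.variants.groupby("chrom", sort=False)["pos"].max()
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haplogwas\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={int(length) + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, row in enumerate(gm.variants.itertuples(index=False)):
            gts = [
                "./." if np.isnan(d) else gt_map[d] for d in gm.dosages[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.chrom}_{row.pos}\t{row.ref}\t"
                f"{row.alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def filter_variants(gm: GenotypeMatrix, spec: VariantFilterSpec | None = None) -> GenotypeMatrix:
    """Keep variants with call rate >= min_call_rate and MAF >= min_maf.

    MAF is computed on non-missing alleles only; ties at either threshold
    are retained ("at least"). Raises if the filter removes everything.
    """
    if spec is None:
        spec = VariantFilterSpec()
    if gm.n_variants == 0:
        raise ValueError("empty genotype matrix")
    keep = (gm.call_rate() >= spec.min_call_rate) & (gm.maf() >= spec.min_maf)
    if not keep.any():
        raise ValueError(
            "variant filter removed all markers "
            f"(min_call_rate={spec.min_call_rate}, min_maf={spec.min_maf})"
        )
    return gm.take_variants(np.flatnonzero(keep))


def snp_density(gm: GenotypeMatrix, window_bp: int) -> pd.DataFrame:
    """Windowed SNP counts per chromosome.

    Returns a long DataFrame (chrom, window_start, window_end, count);
    windows are 1-based closed [start, end] and counts partition the
    panel, so per-chromosome counts sum to the chromosome totals.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    out = []
    for chrom in gm.chromosomes:
        pos = gm.variants.loc[gm.variants["chrom"] == chrom, "pos"].to_numpy()
        n_windows = int(pos.max() - 1) // window_bp + 1
        counts = np.bincount((pos - 1) // window_bp, minlength=n_windows)
        for w, c in enumerate(counts):
            out.append((chrom, w * window_bp + 1, (w + 1) * window_bp, int(c)))
    return pd.DataFrame(out, columns=["chrom", "window_start", "window_end", "count"])


def write_dosage_table(gm: GenotypeMatrix, path: str) -> None:
    """Export dosages as a TSV with samples in rows, variants in columns."""
    cols = [f"{r.chrom}:{r.pos}" for r in gm.variants.itertuples(index=False)]
    pd.DataFrame(gm.dosages, index=gm.sample_ids, columns=cols).to_csv(
        path, sep="\t", index_label="sample", na_rep="NA"
    )
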