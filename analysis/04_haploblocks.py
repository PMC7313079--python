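"""Partition each chromosome into haploblocks (Gabriel CI method).

Pairs of markers are classified strong-LD / recombination from
likelihood CIs on |D'| (thresholds 0.7 / 0.98, recombination below
0.9); maximal marker runs dominated by strong-LD pairs become blocks.
Compares the inferred blocks against the planted ground truth.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import OUTDIR, config

from haplogwas import genio, ld
from haplogwas.pipeline import run_pipeline

run_pipeline(config(), stages=["blocks"])

blocks = ld.read_blocks_text(f"{OUTDIR}/blocks.tsv")
n_snps = sum(b.n_snps for b in blocks)
print(f"{len(blocks)} haploblocks covering {n_snps} SNPs "
      f"(mean {n_snps / max(len(blocks), 1):.1f} SNPs/block)")

truth = json.loads(Path(f"{OUTDIR}/truth.json").read_text())
gm_raw = genio.read_vcf(f"{OUTDIR}/genotypes.vcf")
gm = genio.read_vcf(f"{OUTDIR}/filtered.vcf")
key = {(r.chrom, r.pos): i for i, r in enumerate(gm.variants.itertuples(index=False))}
raw = gm_raw.variants
inferred = [set(b.member_snps) for b in blocks]
jaccs = []
for bid, idxs in truth["block_variants"].items():
    planted = {key[(raw["chrom"][i], raw["pos"][i])] for i in idxs
               if (raw["chrom"][i], raw["pos"][i]) in key}
    if len(planted) < 2:
        continue
    jaccs.append(max((len(planted & s) / len(planted | s) for s in inferred),
                     default=0.0))
print(f"recovery of {len(jaccs)} planted blocks: "
      f"mean Jaccard {sum(jaccs) / len(jaccs):.3f}")
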