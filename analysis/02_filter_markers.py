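"""Apply the marker filters: call rate >= 90%, MAF >= 3%.

Reports how many SNPs survive and the per-chromosome density, mirroring
the raw-panel summary of a reduced-representation genotyping study.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import OUTDIR, config

from haplogwas import genio
from haplogwas.pipeline import run_pipeline

run_pipeline(config(), stages=["filter"])

gm = genio.read_vcf(f"{OUTDIR}/filtered.vcf")
print(f"{gm.n_variants} SNPs retained across {len(gm.chromosomes)} chromosomes")
per_chrom = gm.variants.groupby("chrom", sort=False).size()
print(per_chrom.to_string())
dens = pd.read_csv(f"{OUTDIR}/snp_density.tsv", sep="\t")
busiest = dens.nlargest(3, "count")
print("densest 1-Mb windows:")
print(busiest.to_string(index=False))
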