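"""Generate the synthetic landrace panel.

Simulates ~400 selfing accessions on 8 chromosomes with 40 planted
founder-haplotype blocks, 10 phenotypes (two 3-trait pleiotropy groups,
two single-block traits, two null traits), collection-site coordinates
for 6 geographic groups, and 19 block-correlated bioclimatic variables.
Writes genotypes.vcf, traits.tsv, coords.tsv and the ground-truth JSON.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import config

from haplogwas.pipeline import run_pipeline

manifest = run_pipeline(config(), stages=["simulate"])
print("wrote:", *manifest["outputs"].values(), sep="\n  ")
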