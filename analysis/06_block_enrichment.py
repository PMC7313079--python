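"""Haploblock set-enrichment over the GWAS p-value rankings.

Blocks with more than six SNPs are tested per trait with the GSEA-style
running-sum statistic against 100,000 same-size random SNP sets; a block
is significantly enriched when its ES is positive and the within-trait
BH q-value is below 0.05.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import OUTDIR, config

from haplogwas.pipeline import run_pipeline

run_pipeline(config(), stages=["enrich"])

res = pd.read_csv(f"{OUTDIR}/enrichment.tsv", sep="\t")
sig = res[res["significant"]]
print(f"{len(sig)} significant (block, trait) pairs of {len(res)} tested")
by_trait = sig.groupby("trait").size().sort_values(ascending=False)
print("traits with enriched blocks:")
print(by_trait.to_string())
sets = json.loads(Path(f"{OUTDIR}/enriched_sets.json").read_text())
empty = [t for t, s in sets.items() if not s]
print(f"{len(empty)} traits with no enriched block")
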