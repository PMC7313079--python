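"""Bi-cluster traits by shared enriched haploblocks.

The Dice overlap of two traits' enriched-block sets measures shared
genetic architecture; average-linkage clustering of 1 - Dice applied to
both axes of the trait x trait matrix reveals pleiotropy groups.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import OUTDIR, config

from haplogwas.pipeline import run_pipeline

run_pipeline(config(), stages=["similarity"])

groups = json.loads(Path(f"{OUTDIR}/trait_groups.json").read_text())
by_group: dict[int, list[str]] = {}
for trait, g in groups.items():
    by_group.setdefault(g, []).append(trait)
multi = {g: ts for g, ts in by_group.items() if len(ts) > 1}
print(f"{len(multi)} multi-trait groups at the default cut height:")
for g, ts in sorted(multi.items()):
    print(f"  group {g}: {', '.join(sorted(ts))}")

sim = pd.read_csv(f"{OUTDIR}/similarity.tsv", sep="\t", index_col="trait")
pairs = sim.where(~(sim.columns.to_numpy() == sim.index.to_numpy()[:, None]))
top = pairs.stack().sort_values(ascending=False).head(5)
print("highest trait-trait similarities:")
print(top.to_string())
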