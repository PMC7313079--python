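"""Descriptive statistics: trait correlations, nucleotide diversity and
between-group bioclim differences.

Spearman matrices verify the planted correlation blocks among the 19
bioclimatic variables; per-group, per-chromosome pi (over polymorphic
sites) compares genomic diversity between geographic groups; the
Mann-Whitney test screens bioclim variables for group differences.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from common import OUTDIR

from haplogwas import genio, stats as dstats
from haplogwas.simulate import read_trait_table

out = Path(OUTDIR)
gm = genio.read_vcf(str(out / "filtered.vcf"))
traits = read_trait_table(out / "traits.tsv").loc[gm.sample_ids]
truth = json.loads((out / "truth.json").read_text())
groups = np.asarray(truth["group_labels"])

bio = traits[[c for c in traits.columns if c.startswith("BIO")]]
cm = dstats.spearman_matrix(bio)
cm.r.to_csv(out / "bioclim_spearman.tsv", sep="\t")
r = cm.r.to_numpy()
off = r[~np.eye(len(r), dtype=bool)]
print(f"bioclim Spearman: {np.nanmean(np.abs(off)):.2f} mean |r|, "
      f"{(off > 0.7).sum() // 2} pairs with r > 0.7")

pi = dstats.site_pi(gm, groups)
pi.to_csv(out / "pi_by_group.tsv", sep="\t", index=False)
per_group = pi.groupby("group")["pi"].mean()
print("mean per-site pi by geographic group:")
print(per_group.round(4).to_string())

mw = dstats.mann_whitney_groups(bio["BIO1"].to_numpy(), groups)
mw.to_csv(out / "bio1_group_tests.tsv", sep="\t", index=False)
n_sig = (mw["p"] < 0.05).sum()
print(f"BIO1 differs between {n_sig} of {len(mw)} group pairs (p < 0.05)")
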