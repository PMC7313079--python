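"""Characterize LD: unlinked critical r2 and the LOESS decay range.

The 95th parametric percentile of cross-chromosome r2 gives the critical
value below which linkage is indistinguishable from background; the
distance at which the second-degree LOESS of intra-chromosomal r2 first
drops to that value estimates the physical range of LD in the panel.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import OUTDIR, config

from haplogwas.pipeline import run_pipeline

run_pipeline(config(), stages=["ld"])

summary = json.loads(Path(f"{OUTDIR}/ld_summary.json").read_text())
print(f"critical r2 ({summary['critical_mode']}): {summary['critical_r2']:.4f} "
      f"from {summary['n_unlinked_pairs']} unlinked pairs")
rng = summary["decay_range_bp"]
if rng is None:
    print("LOESS curve never reaches the critical value (LD decays beyond "
          "the observed distances)")
else:
    print(f"LD decay range: {rng / 1000:.0f} kb "
          f"({summary['n_intra_pairs']} intra-chromosomal pairs)")
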