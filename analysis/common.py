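"""Shared configuration for the numbered analysis drivers.

All drivers write under results/analysis and share one global seed, so
the sequence 01..08 reproduces a single coherent study end to end.
"""

from haplogwas.pipeline import PipelineConfig

OUTDIR = "results/analysis"
SEED = 2026


def config() -> PipelineConfig:
    return PipelineConfig(outdir=OUTDIR, seed=SEED, n_perm=100_000)
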