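import numpy as np
import pandas as pd
import pytest

from haplogwas.genio import GenotypeMatrix
from haplogwas.simulate import PlantedBlock, SimConfig, simulate_genotypes


def make_gm(dosages, chrom="Ca1", start=1000, step=1000, sample_prefix="S"):
    """GenotypeMatrix from a plain dosage array with evenly spaced positions."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * m if isinstance(chrom, str) else chrom,
            "pos": np.arange(start, start + m * step, step),
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    return GenotypeMatrix(d, [f"{sample_prefix}{i}" for i in range(n)], variants)


@pytest.fixture(scope="session")
def two_block_panel():
    """n=400 panel: one chromosome with two planted 6-SNP blocks, free
    recombination elsewhere; plus a second chromosome of background SNPs."""
    cfg = SimConfig(
        n_samples=400,
        chromosomes=(("Ca1", 6_000_000, 30), ("Ca2", 6_000_000, 20)),
        block_spec=(
            PlantedBlock("Ca1", 1_000_000, 1_150_000, 6, 2),
            PlantedBlock("Ca1", 4_000_000, 4_180_000, 6, 3),
        ),
        missing_rate=0.01,
        seed=42,
    )
    gm, truth = simulate_genotypes(cfg)
    return gm, truth
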