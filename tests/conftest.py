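import numpy as np
import pandas as pd
import pytest

from devatlas import AtlasSimConfig, ExpressionAtlas, GenomeSimConfig
from devatlas import simulate_atlas, simulate_genome_gwas


def make_atlas(expr: dict, tissues: dict, stages: dict | None = None) -> ExpressionAtlas:
    """Build a small atlas from {gene: [values]} and {sample: tissue}."""
    samples = list(tissues)
    expression = pd.DataFrame(expr, index=samples).T
    expression.index.name = "gene_id"
    meta = pd.DataFrame(
        {
            "tissue": [tissues[s] for s in samples],
            "stage": [(stages or {}).get(s, "S1") for s in samples],
            "timepoint": ["tp1"] * len(samples),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionAtlas(expression, meta)


@pytest.fixture(scope="session")
def planted_atlas():
    """Default simulated atlas: 6 tissues x 4 stages, 50 planted
    tissue-specific genes per tissue, effect 4 log2 units, noise 0.3."""
    return simulate_atlas(AtlasSimConfig(seed=11))


@pytest.fixture(scope="session")
def tiled_genome():
    """50 genes tiled over 2 chromosomes with 5000 SNPs, null effects."""
    genes = [f"g{i:04d}" for i in range(50)]
    cfg = GenomeSimConfig(
        n_chromosomes=2, gene_length=15_000, intergenic_gap=30_000,
        n_snps=5_000, seed=5,
    )
    return simulate_genome_gwas(cfg, genes)
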