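import numpy as np
import pandas as pd
import pytest

from xconcord import (
    ExpressionMatrix,
    ProbeCountMatrix,
    SampleAnnotation,
    SimConfig,
    generate_dual_platform,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_probe_matrix():
    """Three genes, one with two probes, two samples."""
    counts = pd.DataFrame(
        {
            "s1": [5, 9, 3, 0],
            "s2": [2, 4, 7, 1],
        },
        index=pd.Index(["p1", "p2", "p3", "p4"], name="probe_id"),
    )
    manifest = pd.DataFrame(
        {
            "gene_symbol": ["A", "A", "B", "C"],
            "ensembl_id": ["ENSG1", "ENSG1", "ENSG2", "ENSG3"],
        },
        index=counts.index,
    )
    return ProbeCountMatrix(counts, manifest)


@pytest.fixture
def small_annotation():
    return SampleAnnotation(
        pd.DataFrame(
            {
                "cell_line": ["CL1", "CL1", "CL2"],
                "platform": ["TARGETED"] * 3,
                "phase": ["1", "1", "1"],
                "replicate": [1, 2, 1],
            },
            index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
        )
    )


def make_epm(values: dict, genes=None) -> ExpressionMatrix:
    df = pd.DataFrame(values, index=genes or [f"g{i}" for i in range(len(next(iter(values.values()))))])
    return ExpressionMatrix(df * (1e6 / df.sum()), "epm")


@pytest.fixture
def dual_platform_small():
    cfg = SimConfig(n_genes=300, n_cell_lines=5, n_replicates_per_platform=2, seed=11)
    return cfg, *generate_dual_platform(cfg)
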