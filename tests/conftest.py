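import numpy as np
import pandas as pd
import pytest

import seqconverge as sc


@pytest.fixture(scope="session")
def small_config():
    """A small but fully structured study for fast end-to-end tests."""
    return sc.SimulationConfig(
        n_genes=400,
        n_celltype_genes=40,
        n_shared_treatment_genes=20,
        n_treatment_genes=10,
        n_dormant_genes=30,
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    counts, truth = sc.simulate_expression(small_config)
    return counts, truth


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return sc.simulate_annotation(small_config)


@pytest.fixture(scope="session")
def quantified(small_study):
    counts, _ = small_study
    return sc.quantify_pipeline(counts)


@pytest.fixture()
def design_2x4x3():
    """Balanced 2 cell types x 4 treatments x 3 replicates metadata."""
    rows = []
    for ct in ("adipocyte", "macrophage"):
        for tr in ("NS", "IFNB", "LPS", "IFNB_LPS"):
            for rep in (1, 2, 3):
                rows.append((f"{ct}_{tr}_{rep}", ct, tr, rep))
    return pd.DataFrame(
        rows, columns=["sample_id", "cell_type", "treatment", "replicate"]
    ).set_index("sample_id")


def make_counts(counts, lengths, metadata):
    """Assemble a CountMatrix from plain arrays for hand examples."""
    return sc.CountMatrix(
        counts=counts, lengths=lengths, metadata=metadata
    )


@pytest.fixture()
def tiny_metadata():
    return pd.DataFrame(
        {
            "cell_type": ["adipocyte", "macrophage"],
            "treatment": ["NS", "NS"],
            "replicate": [1, 1],
        },
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )
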