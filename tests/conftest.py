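import numpy as np
import pandas as pd
import pytest

from serostrat import (
    IntensityMatrix,
    PartitionConfig,
    SyntheticConfig,
    adjust_matrix,
    generate_proteome,
    run_consensus_pipeline,
)


def make_matrix(values, peptide_counts=None, protein_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    p, s = values.shape
    protein_ids = protein_ids or [f"P{i}" for i in range(p)]
    sample_ids = sample_ids or [f"S{j}" for j in range(s)]
    df = pd.DataFrame(values, index=protein_ids, columns=sample_ids)
    pep = None
    if peptide_counts is not None:
        pep = pd.Series(peptide_counts, index=protein_ids)
    return IntensityMatrix(df, pep)


@pytest.fixture(scope="session")
def planted_dataset():
    """Four well-separated planted groups at a desk-friendly size."""
    cfg = SyntheticConfig(
        n_samples=80, n_proteins=200, n_groups=4, block_effect=3.0, seed=11
    )
    matrix, truth = generate_proteome(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def planted_qc(planted_dataset):
    cfg, matrix, truth = planted_dataset
    qc_matrix, report = adjust_matrix(matrix)
    return cfg, qc_matrix, truth, report


@pytest.fixture(scope="session")
def planted_consensus(planted_qc):
    cfg, qc_matrix, truth, _ = planted_qc
    result = run_consensus_pipeline(
        qc_matrix, PartitionConfig(n_repeats=30, seed=11)
    )
    return qc_matrix, truth, result
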