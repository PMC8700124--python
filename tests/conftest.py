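import numpy as np
import pandas as pd
import pytest

from mitofunnel import AbundanceMatrix, PipelineConfig, SimConfig, generate_dataset
from mitofunnel.simulate import sample_table


def make_matrix(values, replicates_per_group=3, protein_ids=None, unique_peptides=None):
    """AbundanceMatrix over the full 2x3xR design from a raw array."""
    meta = sample_table(replicates_per_group)
    values = np.asarray(values, dtype=float)
    if protein_ids is None:
        protein_ids = [f"P{i}" for i in range(values.shape[0])]
    up = None
    if unique_peptides is not None:
        up = pd.Series(unique_peptides, index=protein_ids)
    return AbundanceMatrix(
        values=pd.DataFrame(values, index=protein_ids, columns=meta.index),
        samples=meta,
        unique_peptides=up,
    )


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def small_noisy_dataset():
    cfg = SimConfig(n_proteins=120, seed=11)
    return generate_dataset(cfg), cfg


@pytest.fixture
def zero_noise_dataset():
    cfg = SimConfig(n_proteins=100, noise_sd=0.0, frac_single_peptide=0.0, seed=7)
    return generate_dataset(cfg), cfg
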