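import numpy as np
import pandas as pd
import pytest

from ecmnet import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """120-sample synthetic cohort with default latent-program structure."""
    spec = synthetic.SyntheticCohortSpec(n_samples=120, seed=42)
    matrix, clinical, truth = synthetic.generate_cohort(spec)
    return matrix, clinical, truth, spec


def make_block_matrix(n_blocks=3, n_proteins=60, n_samples=120, rho=0.8, seed=0):
    """Block-correlated protein matrix from the single-factor model."""
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for b in range(n_blocks):
        a = rng.standard_normal(n_samples)
        eps = rng.standard_normal((n_proteins, n_samples))
        blocks.append(np.sqrt(rho) * a[None, :] + np.sqrt(1 - rho) * eps)
        labels += [b] * n_proteins
    df = pd.DataFrame(
        np.vstack(blocks),
        index=[f"p{i:03d}" for i in range(n_blocks * n_proteins)],
        columns=[f"s{j:03d}" for j in range(n_samples)],
    )
    return df, np.array(labels)


@pytest.fixture
def block_matrix():
    return make_block_matrix()
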