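import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gcsubtype import ExpressionMatrix, SimulationConfig, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def make_matrix(values, sample_ids=None, gene_ids=None, tissue_types=None,
                cohort="0", scale="log2"):
    """Small helper: ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    ann = pd.DataFrame(
        {
            "tissue_type": tissue_types or ["tumor"] * n_samples,
            "cohort": cohort,
        },
        index=sample_ids,
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), ann, scale=scale
    )


@pytest.fixture(scope="session")
def strong_cohort():
    """One well-separated cohort with ground truth (shared, read-only)."""
    config = SimulationConfig(
        n_cohorts=1, samples_per_cohort=80, n_genes=800, n_signature_genes=60,
        effect_size=3.0, gene_noise_sd=0.8, seed=42,
    )
    matrix, clinical, truth = generate_cohort(config, 0)
    return config, matrix, clinical, truth
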