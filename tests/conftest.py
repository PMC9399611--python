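import numpy as np
import pandas as pd
import pytest

from tmephenotype import GeneratorConfig, generate_cohort
from tmephenotype.io_preprocess import ExpressionMatrix


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across tests."""
    cfg = GeneratorConfig(
        seed=7,
        n_samples=90,
        n_genes=600,
        n_null_genes=60,
        n_differential_genes=6,
        n_cnv_units=60,
        n_sc_samples=4,
        cells_per_sample=15,
        umis_per_cell=800,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def random_expression(rng, n_genes=30, n_samples=5, log_scale=True, batch=None):
    vals = pd.DataFrame(
        rng.normal(6, 2, size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix(vals, log_scale=log_scale, batch=batch)
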