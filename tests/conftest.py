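import numpy as np
import pandas as pd
import pytest

from notchcall import (
    CohortSpec,
    ExpressionMatrix,
    GeneSignature,
    default_signature,
    simulate_expression_cohort,
)


@pytest.fixture(scope="session")
def signature() -> GeneSignature:
    return default_signature()


@pytest.fixture(scope="session")
def tiny_signature() -> GeneSignature:
    return GeneSignature(name="TINY", up_genes=["U1", "U2"], down_genes=["D1", "D2"])


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(30)]
    samples = [f"s{j}" for j in range(6)]
    return ExpressionMatrix(genes, samples, rng.poisson(50, (30, 6)).astype(float))


@pytest.fixture(scope="session")
def labeled_cohort(signature):
    """A separated two-class cohort with truth labels (strong activation)."""
    spec = CohortSpec(
        n_activated=10,
        n_wildtype=10,
        n_genes=500,
        up_effect=4.0,
        down_effect=0.25,
        dispersion=0.1,
        seed=20240901,
    )
    matrix, meta, truth = simulate_expression_cohort(spec, signature)
    return matrix, meta, truth
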