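import numpy as np
import pandas as pd
import pytest

from drsynergy import (
    ModelSpec,
    SimulationConfig,
    simulate_cohort,
)
from drsynergy.containers import SAMPLE_FIELDS, ExpressionMatrix
from drsynergy.synergy_models import train
from drsynergy.workflows import cohort_signatures, regime_dataset


def make_expression(gene_values: dict, sample_meta: dict) -> ExpressionMatrix:
    """Build a small ExpressionMatrix from {gene: [values]} and {sample: meta tuple}."""
    samples = pd.DataFrame(
        [sample_meta[s] for s in sample_meta],
        index=pd.Index(list(sample_meta), name="sample_id"),
        columns=list(SAMPLE_FIELDS),
    )
    values = pd.DataFrame(gene_values, index=list(sample_meta)).T
    values.index.name = "gene"
    return ExpressionMatrix(values=values, samples=samples)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small, fast cohort: 60 genes, 12 cell lines, 4 drugs, 2 programs."""
    return simulate_cohort(
        SimulationConfig(
            n_genes=60, n_cell_lines=12, n_drugs=4, n_programs=2,
            genes_per_program=5, n_fingerprint_bits=16, seed=7,
        )
    )


@pytest.fixture(scope="session")
def reference_cohort():
    """The default study cohort (1000 genes, 80 cell lines, 10 drugs, 4 programs)."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def drs_signatures(reference_cohort):
    return cohort_signatures(reference_cohort, kind="DRS")


@pytest.fixture(scope="session")
def drs_dataset(reference_cohort, drs_signatures):
    return regime_dataset(reference_cohort, "DRS", signatures=drs_signatures)


@pytest.fixture(scope="session")
def structure_dataset(reference_cohort, drs_dataset):
    return regime_dataset(
        reference_cohort, "structure", context_genes=drs_dataset.spec.gene_subset
    )


@pytest.fixture(scope="session")
def drs_xgb_model(drs_dataset):
    return train(drs_dataset, ModelSpec("xgb", seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
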