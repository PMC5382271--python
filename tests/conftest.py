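import numpy as np
import pytest

from termscan import core_model as cm
from termscan import synthetic_data as sd


@pytest.fixture(scope="session")
def cohort_config():
    """Default study conditions: 200 genes, depth 20, theta 0.05 vs 0.40."""
    return sd.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def cohort(cohort_config):
    genes, sequences, planted = sd.simulate_genome(cohort_config)
    expression = sd.gene_expression(genes, cohort_config)
    return {
        "config": cohort_config,
        "genes": genes,
        "sequences": sequences,
        "planted": planted,
        "expression": expression,
    }


@pytest.fixture(scope="session")
def filtered_genes(cohort):
    return cm.filter_genes(cohort["genes"])


@pytest.fixture()
def tiny_genes():
    """Two hand-placed genes, one per strand, on a 2 kb chromosome."""
    genes = [
        cm.GeneModel("plusg", "chr1", "+", 100, 700),
        cm.GeneModel("minusg", "chr1", "-", 1200, 1800),
    ]
    return cm.GeneSet(genes, {"chr1": 2000}).with_downstream_gaps()


def constant_coverage(genes, value=0.0):
    cov = cm.StrandedCoverage(genes.chrom_sizes)
    for chrom, size in genes.chrom_sizes.items():
        for strand in "+-":
            cov.set(chrom, strand, np.full(size, float(value)))
    return cov
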