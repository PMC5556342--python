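import numpy as np
import pytest

from dupdepth import FamilySpec, OracleAligner, make_toy_genome, make_worked_example


@pytest.fixture(scope="session")
def toy_truth():
    """Small diverged family: 2 genes x (CON1, HLS1) x 2 domains, 5%
    within-gene and 8% between-gene divergence."""
    spec = FamilySpec(
        n_genes=2,
        clades=("CON1", "HLS1"),
        domains_per_clade=2,
        divergence_within=0.05,
        divergence_between=0.08,
        domain_length=600,
        intergenic_length=4000,
        intra_gene_spacer=300,
        seed=13,
    )
    return make_toy_genome(spec)


@pytest.fixture(scope="session")
def toy_oracle(toy_truth):
    return OracleAligner(toy_truth.reference)


@pytest.fixture(scope="session")
def worked_example():
    return make_worked_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
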