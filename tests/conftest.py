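"""Shared fixtures: a small simulated dataset and a hand-crafted QC matrix."""

import pytest

from synotreg.simulate import SimConfig, generate_dataset
from synotreg.testing import crafted_qc_fixture


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SimConfig(
        n_cells_pb=300, n_cells_sf=300, n_genes=400, n_clusters=5,
        n_module_genes=15, mito_gene_count=5, n_expanded_clones=5,
        expanded_size_mean=12.0, sf_bias=0.9, seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def qc_fixture():
    """(matrix, chains, expected_kept, expected_rule_of_removed)."""
    return crafted_qc_fixture()
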