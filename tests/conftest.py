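import pytest

from herbnet import tables
from herbnet.fixtures import SyntheticConfig, paper_preset


@pytest.fixture
def reference_compounds():
    """The five packaged active compounds."""
    return tables.active_compounds()


@pytest.fixture
def reference_targets():
    """The packaged 41-gene drug/disease intersection set."""
    return tables.intersection_targets()


@pytest.fixture
def paper_cfg() -> SyntheticConfig:
    """Study-condition synthetic config at the default seed."""
    return paper_preset(seed=7)


@pytest.fixture
def small_cfg() -> SyntheticConfig:
    """A fast, small synthetic config for generator unit tests."""
    return SyntheticConfig(
        seed=11,
        n_ingredients=20,
        pass_fraction=0.25,
        n_universe=400,
        n_drug_targets=30,
        n_disease_targets=80,
        n_overlap=10,
        inject_reference_targets=False,
        ppi_nodes=25,
        ppi_edges=60,
        ppi_planted_hubs=3,
        hub_degree_factor=2.0,
        n_terms=15,
        planted_term_size=12,
        planted_overlap=8,
        query_size=20,
        annotation_universe=300,
    )
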