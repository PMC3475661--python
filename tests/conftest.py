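import numpy as np
import pandas as pd
import pytest

import tfnetevo as t


@pytest.fixture(scope="session")
def small_config() -> t.GeneratorConfig:
    """Desk-scale generator conditions for fast unit tests."""
    return t.GeneratorConfig(n_genes=400, n_tfs=40, out_degree_min=5,
                             out_degree_max=30)


@pytest.fixture(scope="session")
def small_bundle(small_config) -> t.SyntheticBundle:
    return t.generate_bundle(small_config, seed=7)


@pytest.fixture(scope="session")
def small_genes(small_bundle) -> t.GeneTable:
    genes = t.assign_missing_ortholog_rate(small_bundle.genes)
    return genes.with_ranks(["assigned_ka_ks", "expression", "cai"])


@pytest.fixture(scope="session")
def small_net(small_bundle) -> t.RegulatoryNetwork:
    return t.build_regulatory_network(small_bundle.edge_records).select_source("chip")


@pytest.fixture()
def toy_gene_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": ["a", "b", "c"],
            "ka_ks": [0.1, 0.5, np.nan],
            "expression": [10.0, 5.0, 2.0],
            "cai": [0.8, 0.5, 0.3],
            "is_tf": [False, True, False],
            "ortholog_par": [True, True, False],
            "ortholog_mik": [True, True, True],
        }
    )
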