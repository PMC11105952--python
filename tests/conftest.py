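import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from orthoenrich.enrich import DETable
from orthoenrich.genesets import GeneSet
from orthoenrich.idmap import MappingTable
from orthoenrich.simdata import SimConfig

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_mapping():
    """Three genes fully covered across all four namespaces."""
    return MappingTable(
        pd.DataFrame(
            {
                "ncbi": ["100", "101", "102"],
                "ensembl": ["ENSDARG1", "ENSDARG2", "ENSDARG3"],
                "zfin": ["ZDB-1", "ZDB-2", "ZDB-3"],
                "symbol": ["cyp1a", "sox2", "tp53"],
            }
        )
    )


@pytest.fixture
def toy_de():
    """Four-gene universe: g1, g3 significant; g1, g2 upregulated."""
    return DETable(
        pd.DataFrame(
            {
                "gene": ["g1", "g2", "g3", "g4"],
                "pvalue": [0.01, 0.5, 0.02, 0.9],
                "log2fc": [1.5, 2.0, -1.0, -0.2],
            }
        )
    )


@pytest.fixture
def toy_set():
    return GeneSet("dre90001", "toy set", frozenset({"g1", "g2"}))


@pytest.fixture
def small_cfg():
    return SimConfig(
        n_zfish_genes=300,
        n_human_genes=300,
        n_sets=20,
        set_size_range=(5, 25),
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
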