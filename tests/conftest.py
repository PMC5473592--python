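import pandas as pd
import pytest

from repliseq.otu_table import OTUTable, TaxonomyMap
from repliseq.synthetic_data import preset_study


@pytest.fixture
def toy_table():
    """4 OTUs x 4 datasets from 2 samples, small enough to check by hand."""
    counts = pd.DataFrame(
        {
            "A_r1": [5, 3, 0, 1],
            "A_r2": [4, 4, 1, 0],
            "B_r1": [0, 1, 6, 3],
            "B_r2": [1, 0, 5, 4],
        },
        index=["o1", "o2", "o3", "o4"],
    )
    return OTUTable(
        counts, {"A_r1": "A", "A_r2": "A", "B_r1": "B", "B_r2": "B"}
    )


@pytest.fixture
def toy_tax():
    ids = ["o1", "o2", "o3", "o4"]
    return TaxonomyMap(
        lineage=pd.Series(["Eukaryota;SAR"] * 4, index=ids),
        category=pd.Series(["protist", "metazoa", "protist", "other"], index=ids),
    )


@pytest.fixture(scope="session")
def tiny_study():
    """Small synthetic study (3 samples x 3 replicates, 200 OTUs)."""
    return preset_study("tiny", seed=7)
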