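import numpy as np
import pandas as pd
import pytest

from ncoocnet.tabular_io import AbundanceTable, SoilMetadata


@pytest.fixture
def small_table() -> AbundanceTable:
    """3 OTUs x 4 samples, two groups of two."""
    counts = pd.DataFrame(
        {
            "CK_1": [10, 5, 0],
            "CK_2": [8, 6, 1],
            "AR_1": [2, 9, 4],
            "AR_2": [3, 7, 5],
        },
        index=["OTU_1", "OTU_2", "OTU_3"],
    )
    taxonomy = pd.Series(
        [
            "Bacteria;Proteobacteria;g__Bradyrhizobium",
            "Bacteria;Proteobacteria;g__Rhodanobacter",
            "Archaea;Crenarchaeota;g__Nitrososphaera",
        ],
        index=counts.index,
    )
    group = pd.Series(["CK", "CK", "AR", "AR"], index=counts.columns)
    return AbundanceTable(counts=counts, taxonomy=taxonomy, group=group)


@pytest.fixture
def small_metadata(small_table) -> SoilMetadata:
    data = pd.DataFrame(
        {
            "pH": [5.1, 5.0, 4.7, 4.8],
            "AP": [21.0, 19.5, 22.3, 20.8],
        },
        index=small_table.sample_ids,
    )
    return SoilMetadata(data=data)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
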