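import numpy as np
import pandas as pd
import pytest

from ribophase.io_tables import OtuTable, TaxonomyMap


@pytest.fixture
def tiny_counts() -> pd.DataFrame:
    return pd.DataFrame(
        [[5, 0, 1], [2, 3, 0]],
        index=pd.Index(["S1", "S2"], name="sample_id"),
        columns=["OTU1", "OTU2", "OTU3"],
    )


@pytest.fixture
def tiny_table(tiny_counts) -> OtuTable:
    return OtuTable(tiny_counts.copy())


@pytest.fixture
def tiny_taxonomy() -> TaxonomyMap:
    return TaxonomyMap(
        pd.DataFrame(
            {
                "supergroup": ["Alveolata", "Metazoa", "Hacrobia"],
                "group": ["Dinophyceae", "Copepoda", "Haptophyta"],
                "closest_relative": ["Gyrodinium_spirale", "Calanus_sp", "Phaeocystis_globosa"],
                "pct_identity": [99.0, 98.0, 99.1],
            },
            index=pd.Index(["OTU1", "OTU2", "OTU3"], name="otu_id"),
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130226)
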