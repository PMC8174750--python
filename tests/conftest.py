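import numpy as np
import pandas as pd
import pytest

from mycoassembly.data_io import CountTable


@pytest.fixture
def toy_table():
    """3 samples x 4 ASVs with simple hand-checkable counts."""
    return CountTable(
        pd.DataFrame(
            [[6, 4, 0, 0], [2, 8, 0, 0], [0, 0, 5, 5]],
            index=["s1", "s2", "s3"],
            columns=["a1", "a2", "a3", "a4"],
        )
    )


@pytest.fixture
def toy_taxonomy():
    return pd.DataFrame(
        {
            "domain": ["Fungi", "Fungi", "Fungi", "Viridiplantae"],
            "phylum": ["Ascomycota", "Ascomycota", "Chytridiomycota", "unclassified"],
            "class": ["unclassified"] * 4,
            "order": ["Pleosporales", "Pleosporales", "Chytridiales", "unclassified"],
            "family": ["unclassified"] * 4,
            "genus": ["unclassified"] * 4,
            "species": ["unclassified"] * 4,
        },
        index=pd.Index(["a1", "a2", "a3", "a4"], name="asv_id"),
    )


@pytest.fixture
def toy_metadata():
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "site_code": ["BB", "BB", "SD"],
            "ocean": ["Pacific"] * 3,
            "sample_type": ["leaf", "leaf", "leaf"],
            "latitude": [38.319755, 38.319755, 32.713756],
            "longitude": [-123.05514, -123.05514, -117.22547],
            "individual": [1, 2, 1],
        }
    )
    return meta.set_index("sample_id", drop=False)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
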