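from pathlib import Path

import pandas as pd
import pytest

from qpcrsig import (
    SignatureDefinition,
    read_ct_table,
    synthetic_signature,
)

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def mini_signature() -> SignatureDefinition:
    """Four scored genes + the two housekeeping genes, as in the shipped
    six-sample QC fixture."""
    return SignatureDefinition(
        genes=("AVL9", "PCMTD2", "NCLN", "MAP4K4"),
        direction={
            "AVL9": "up_in_pos",
            "PCMTD2": "up_in_pos",
            "NCLN": "down_in_pos",
            "MAP4K4": "down_in_pos",
        },
    )


@pytest.fixture(scope="session")
def qc_fixture_table() -> pd.DataFrame:
    return read_ct_table(DATA / "qc_fixture_ct.csv")


@pytest.fixture(scope="session")
def sig20() -> SignatureDefinition:
    return synthetic_signature()
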