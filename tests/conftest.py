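import numpy as np
import pandas as pd
import pytest

from viroshot.annotation import HIT_COLUMNS

_HIT_DEFAULTS = {
    "subject_id": "s1",
    "percent_identity": 90.0,
    "bit_score": 50.0,
    "database": "nr",
    "subject_description": "hypothetical protein",
    "source_category": "bacteria",
}


def hit(query_id, evalue, **kwargs):
    """One hit-table row with sensible defaults."""
    row = {"query_id": query_id, "evalue": evalue, **_HIT_DEFAULTS}
    row.update(kwargs)
    return row


def make_hits(rows) -> pd.DataFrame:
    """Build a hit table from `hit(...)` rows (column order enforced)."""
    return pd.DataFrame(list(rows), columns=HIT_COLUMNS)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
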