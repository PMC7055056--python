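import numpy as np
import pytest

from microcensus import TaxonTable


@pytest.fixture
def toy_table() -> TaxonTable:
    """2 samples x 2 taxa: counts [[3, 0], [1, 2]]."""
    return TaxonTable.from_dense(
        [[3, 0], [1, 2]], sample_ids=["s1", "s2"], taxon_ids=["tA", "tB"]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
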