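import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_psm():
    """Two proteins, two replicates, both fractions; hand-checkable ppm."""
    rows = []
    for replicate in (1, 2):
        rows += [
            ("P1", replicate, "pellet", 40), ("P2", replicate, "pellet", 10),
            ("P1", replicate, "lysate", 5), ("P2", replicate, "lysate", 45),
        ]
    return pd.DataFrame(rows, columns=[
        "protein_id", "replicate", "fraction", "psm_count",
    ])
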