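import numpy as np
import pandas as pd
import pytest

from swabshade.io import CommunityTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_table():
    """3 samples x 4 ASVs with simple integer counts."""
    df = pd.DataFrame(
        [[6, 2, 2, 0], [2, 2, 0, 4], [0, 0, 5, 5]],
        index=["S1", "S2", "S3"],
        columns=["A1", "A2", "A3", "A4"],
    )
    return CommunityTable(df, mode="counts")


def random_count_table(rng, n_samples=None, n_asvs=None, max_count=50):
    """Random small counts table with no all-zero rows."""
    n_samples = n_samples or int(rng.integers(2, 11))
    n_asvs = n_asvs or int(rng.integers(2, 13))
    while True:
        counts = rng.integers(0, max_count, size=(n_samples, n_asvs))
        if (counts.sum(axis=1) > 0).all():
            break
    df = pd.DataFrame(
        counts,
        index=[f"S{i}" for i in range(n_samples)],
        columns=[f"A{j}" for j in range(n_asvs)],
    )
    return CommunityTable(df, mode="counts")
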