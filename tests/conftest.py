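import numpy as np
import pandas as pd
import pytest

from supersim.io import MethylationMatrix, PairSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix():
    """3 probes x 4 samples with one missing value."""
    beta = pd.DataFrame(
        {
            "s1": [0.2, 0.5, 0.9],
            "s2": [0.2, 0.6, 0.8],
            "s3": [0.4, np.nan, 0.7],
            "s4": [0.6, 0.5, 0.1],
        },
        index=["p1", "p2", "p3"],
    )
    return MethylationMatrix(beta)


def random_matrix(rng, n_probes, n_samples, missing_rate=0.0):
    beta = rng.random((n_probes, n_samples))
    if missing_rate:
        beta[rng.random(beta.shape) < missing_rate] = np.nan
    frame = pd.DataFrame(
        beta,
        index=[f"p{i}" for i in range(n_probes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return MethylationMatrix(frame)


def consecutive_pairs(sample_ids, pair_class="MZ"):
    ids = list(sample_ids)
    return PairSet(
        [(ids[i], ids[i + 1]) for i in range(0, len(ids) - 1, 2)], pair_class
    )
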