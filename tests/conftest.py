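import numpy as np
import pytest

from proteosect import AbundanceMatrix, PipelineConfig


def make_matrix(values, mask=None, n_a=None, labels=("A", "B")):
    """Build an AbundanceMatrix from an array, splitting columns into two groups."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if n_a is None:
        n_a = m // 2
    if mask is None:
        mask = np.isnan(values)
    sample_ids = [f"{labels[0]}{j + 1:02d}" for j in range(n_a)] + [
        f"{labels[1]}{j + 1:02d}" for j in range(m - n_a)
    ]
    group_of = {s: (labels[0] if i < n_a else labels[1]) for i, s in enumerate(sample_ids)}
    protein_ids = [f"P{i + 1:03d}" for i in range(n)]
    return AbundanceMatrix(protein_ids, sample_ids, group_of, values, np.asarray(mask, bool))


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
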