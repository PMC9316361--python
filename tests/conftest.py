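import numpy as np
import pytest

from hetmda.graph import AssociationData, SimilarityMatrix
from hetmda.synthetic import SyntheticSpec, generate


def random_similarity(rng: np.random.Generator, k: int) -> SimilarityMatrix:
    """Valid random similarity matrix: symmetric, [0, 1], unit diagonal."""
    a = rng.random((k, k))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return SimilarityMatrix(values=a)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_dataset():
    """4 miRNAs x 3 diseases with two planted groups each; deterministic."""
    return generate(
        SyntheticSpec(
            m=4,
            n=3,
            g_m=2,
            g_d=2,
            sim_noise=0.05,
            block_assoc_prob=np.array([[0.9, 0.1], [0.1, 0.1]]),
            seed=3,
        )
    )


@pytest.fixture
def toy_assoc():
    """Hand-written 3x2 association table used by the protocol oracles."""
    return AssociationData(
        np.array([[1, 0], [0, 1], [1, 1]]),
        ["mir-a", "mir-b", "mir-c"],
        ["dis-x", "dis-y"],
    )
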