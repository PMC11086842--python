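import numpy as np
import pytest

from binsight import ExpressionMatrix, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """20 samples x 5 genes, labeled, values on a positive expression scale."""
    X = rng.uniform(0.0, 12.0, size=(20, 5))
    labels = (rng.random(20) < 0.7).astype(int)
    return ExpressionMatrix(X, [f"S{i}" for i in range(20)],
                            [f"G{j}" for j in range(5)], labels)


@pytest.fixture(scope="session")
def planted_dataset():
    """Default synthetic cohort: 300 x 200, 5 planted (gene, bin) signals."""
    return generate(SyntheticSpec(seed=7))


def literal_binarilization(D: np.ndarray, K: int) -> np.ndarray:
    """Direct transcription of the triple-loop binarilization algorithm:
    column-by-column, bin-by-bin membership tests v >= k/K and v < (k+1)/K,
    with the top bin additionally closed at 1.0."""
    I, J = D.shape
    out = np.zeros((I, J * K), dtype=int)
    for j in range(J):
        for k in range(K):
            for i in range(I):
                v = D[i, j]
                hit = v >= k / K and v < (k + 1) / K
                if k == K - 1 and v == 1.0:
                    hit = True
                out[i, j * K + k] = 1 if hit else 0
    return out
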