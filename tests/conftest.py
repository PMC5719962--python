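import numpy as np
import pytest

from coexnet import ExpressionMatrix
from coexnet.simulate import SyntheticSpec


def recovery_spec(seed: int) -> SyntheticSpec:
    """The documented planted-recovery regime: six 50-gene modules with
    membership strengths in [0.7, 1.0] and noise sd 0.2."""
    return SyntheticSpec(
        n_samples=92,
        modules=[(m, 50, (0.7, 1.0)) for m in range(1, 7)],
        n_background_genes=20,
        n_noninformative_genes=10,
        noise_sd=0.2,
        random_seed=seed,
    )


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """5 genes x 6 samples with hand-chosen presence counts {6,4,3,3,0}."""
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],  # present in 6
            [1.0, 2.0, 0.0, 4.0, 5.0, 0.0],  # present in 4
            [1.0, 0.0, 0.0, 4.0, 5.0, 0.0],  # present in 3
            [0.0, 2.0, np.nan, 4.0, 5.0, 0.0],  # present in 3 (NaN is not presence)
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],  # present in 0
        ]
    )
    return ExpressionMatrix(
        [f"g{i}" for i in range(5)], [f"s{j}" for j in range(6)], values
    )


def random_adjacency(n: int, rng: np.random.Generator) -> np.ndarray:
    """Symmetric adjacency in [0, 1] with zero diagonal."""
    raw = rng.random((n, n))
    A = (raw + raw.T) / 2.0
    np.fill_diagonal(A, 0.0)
    return A
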