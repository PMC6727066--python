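import numpy as np
import pytest

from gclmi.datamodel import AlignedDataset, BipartiteInteractionSet, FeatureTable
from gclmi.synthetic import SyntheticConfig, generate_synthetic_dataset


def make_dataset(M: np.ndarray, F_l: np.ndarray, F_m: np.ndarray) -> AlignedDataset:
    """Wrap raw arrays in an AlignedDataset with generated ids."""
    n_l, n_m = M.shape
    lnc = tuple(f"L{i}" for i in range(n_l))
    mir = tuple(f"m{j}" for j in range(n_m))
    return AlignedDataset(
        interactions=BipartiteInteractionSet(lnc, mir, M),
        lnc_features=FeatureTable(lnc, F_l),
        mir_features=FeatureTable(mir, F_m),
    )


@pytest.fixture
def tiny_dataset() -> AlignedDataset:
    """8 lncRNAs x 6 miRNAs with random binary edges and random features."""
    rng = np.random.default_rng(42)
    M = (rng.random((8, 6)) < 0.3).astype(float)
    M[0, 0] = 1.0  # guarantee at least one edge
    return make_dataset(M, rng.random((8, 4)), rng.random((6, 5)))


@pytest.fixture(scope="session")
def benchmark():
    """The default planted synthetic benchmark plus its hidden truth."""
    return generate_synthetic_dataset(SyntheticConfig())


@pytest.fixture(scope="session")
def benchmark_dataset(benchmark) -> AlignedDataset:
    return benchmark[0]
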