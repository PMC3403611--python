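import numpy as np
import pytest
from scipy import sparse

from katznet.prioritize import WeightedNetwork
from katznet.synthdata import SyntheticScenario


def make_random_network(rng: np.random.Generator, n: int, avg_degree: float = 5.0) -> WeightedNetwork:
    """Random symmetric weighted network with at least one edge."""
    genes = [f"n{i:04d}" for i in range(n)]
    p = min(1.0, avg_degree / max(n - 1, 1))
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < p
    if not keep.any():
        keep[rng.integers(iu.size)] = True
    w = rng.uniform(0.05, 1.0, size=int(keep.sum()))
    rows, cols = iu[keep], ju[keep]
    W = sparse.csr_array(
        (np.concatenate([w, w]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    )
    return WeightedNetwork(genes=genes, W=W)


@pytest.fixture
def small_scenario() -> SyntheticScenario:
    """Scaled-down planted-module study used by fast integration tests."""
    return SyntheticScenario(
        n_genes=300,
        n_module=20,
        n_omim=3,
        n_proteomics=4,
        n_microarray=6,
        rng_seed=11,
    )
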