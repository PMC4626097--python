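import numpy as np
import pytest

from ndatrophy import Connectome, RegionAtlas


@pytest.fixture
def two_node_connectome() -> Connectome:
    """Unit-edge 2-node graph used for all hand-derived closed forms."""
    atlas = RegionAtlas(
        names=("A-L", "A-R"),
        hemispheres=("left", "right"),
        lobes=("temporal", "temporal"),
        homotopic=(1, 0),
    )
    return Connectome(atlas=atlas, C=np.array([[0.0, 1.0], [1.0, 0.0]]))


@pytest.fixture
def two_node_eig(two_node_connectome):
    return two_node_connectome.eigensystem()


def random_connectome(n: int, rng: np.random.Generator, density: float = 1.0) -> Connectome:
    """Dense random weighted connectome with continuous (simple-spectrum) weights."""
    W = rng.uniform(0.2, 1.0, size=(n, n))
    mask = rng.random((n, n)) < density
    np.fill_diagonal(mask, False)
    C = np.triu(W * mask, 1)
    C = C + C.T
    if np.any(C.sum(axis=1) == 0):  # dense enough in practice; guard anyway
        return random_connectome(n, rng, density)
    atlas = RegionAtlas(
        names=tuple(f"r{i}" for i in range(n)),
        hemispheres=("midline",) * n,
        lobes=("frontal",) * n,
        homotopic=(-1,) * n,
    )
    return Connectome(atlas=atlas, C=C)


@pytest.fixture
def random_connectome_factory():
    return random_connectome


@pytest.fixture
def eig10(random_connectome_factory):
    return random_connectome_factory(10, np.random.default_rng(7)).eigensystem()
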