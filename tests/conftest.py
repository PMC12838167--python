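import numpy as np
import pytest

from phagecocktail import datasets
from phagecocktail.panel import SusceptibilityMatrix
from phagecocktail.simulate import MarginalSpec, reconstruct_matrix


@pytest.fixture(scope="session")
def published_spec() -> MarginalSpec:
    return MarginalSpec.published()


@pytest.fixture(scope="session")
def reconstructed(published_spec):
    """Marginal-consistent reconstruction of the 25 x 156 panel (shared:
    the search is the expensive step of the suite)."""
    return reconstruct_matrix(published_spec, seed=1)


@pytest.fixture(scope="session")
def catalog():
    return datasets.phage_catalog()


@pytest.fixture(scope="session")
def catalog_map(catalog):
    return {r.phage_id: r for r in catalog}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture
def small_matrix(rng) -> SusceptibilityMatrix:
    """Seeded 6-phage x 20-strain binary matrix."""
    binary = rng.random((6, 20)) < 0.4
    return SusceptibilityMatrix.from_binary(
        [f"P{i}" for i in range(1, 7)], [f"S{j:02d}" for j in range(1, 21)], binary
    )
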