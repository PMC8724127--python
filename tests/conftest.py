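import numpy as np
import pytest

from hubrank import ConnectivityMatrix, PopulationSpec, generate_population


def adjacency(n, edges, weights=None):
    """Build a ConnectivityMatrix from an edge list (unit weights by default)."""
    w = np.zeros((n, n))
    for k, (i, j) in enumerate(edges):
        value = 1.0 if weights is None else weights[k]
        w[i, j] = w[j, i] = value
    return ConnectivityMatrix(w)


def random_matrix(n, density=0.2, seed=0, weighted=True):
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((n, n)) < density, k=1)
    w = upper * (rng.uniform(0.5, 1.5, (n, n)) if weighted else 1.0)
    w = w + w.T
    return ConnectivityMatrix(w)


@pytest.fixture
def triangle():
    return adjacency(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path3():
    return adjacency(3, [(0, 1), (1, 2)])


@pytest.fixture
def star4():
    """Center node 0 with 4 leaves."""
    return adjacency(5, [(0, i) for i in range(1, 5)])


@pytest.fixture(scope="session")
def small_population():
    """12 noisy subjects on 40 nodes; shared across tests (read-only)."""
    spec = PopulationSpec(
        n_subjects=12,
        n_parcels_per_hemisphere=5,
        rois_per_parcel=4,
        weight_noise_sigma=0.4,
        edge_flip_prob=0.05,
        base_density=0.15,
        seed=42,
    )
    return generate_population(spec)


@pytest.fixture(scope="session")
def clean_population():
    """Zero-noise population: every subject equals the base matrix."""
    spec = PopulationSpec(
        n_subjects=6,
        n_parcels_per_hemisphere=5,
        rois_per_parcel=4,
        weight_noise_sigma=0.0,
        edge_flip_prob=0.0,
        base_density=0.15,
        seed=7,
    )
    return generate_population(spec)
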