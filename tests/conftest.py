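import numpy as np
import pytest

from spacelkit import generate_reference, generate_stack3d


@pytest.fixture(scope="session")
def small_ref():
    return generate_reference(
        n_types=4, n_genes=120, n_cells=200, marker_genes_per_type=15,
        marker_logfc=2.0, seed=5,
    )


@pytest.fixture(scope="session")
def tiny_stack():
    return generate_stack3d(
        n_slices=3, spots_per_slice=200, n_domains=3, batch_shift=0.0, seed=3
    )


@pytest.fixture(scope="session")
def clustered_slice():
    """Three well-separated blobs; every spot's neighbours share its domain.

    This instantiates the regime where the alignment objective can reach
    exactly 1: mutual nearest neighbours never cross domain boundaries.
    """
    rng = np.random.default_rng(17)
    centers = np.array([[0.0, 0.0], [4000.0, 0.0], [2000.0, 3500.0]])
    coords, domains = [], []
    for d, c in enumerate(centers):
        # dense uniform patches avoid sparse fringes, so every spot's k-th
        # mutual neighbour lies within the default overlap threshold
        pts = c + rng.uniform(-300.0, 300.0, size=(64, 2))
        coords.append(pts)
        domains.extend([d] * 64)
    return np.vstack(coords), np.array(domains)
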