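import numpy as np
import pytest

import chromoquant as cq


@pytest.fixture(scope="session")
def alternating_labels_300():
    """±1 compartment labels in alternating 50-bin blocks over 300 bins."""
    return np.where((np.arange(300) // 50) % 2 == 0, 1, -1)


@pytest.fixture(scope="session")
def compartment_matrix(alternating_labels_300):
    """Balanced matrix with a planted A=0.4 checkerboard."""
    m = cq.simulate_hic(
        cq.HicSimSpec(
            n_bins=300,
            compartment_labels=alternating_labels_300,
            compartment_amplitude=0.4,
            depth=200.0,
            seed=11,
        )
    )
    return cq.balance_matrix(m)


@pytest.fixture(scope="session")
def tad_matrix():
    """Raw matrix with 10 planted boundaries, τ=3, well inside the edges."""
    bounds = tuple(int(x) for x in np.linspace(55, 445, 10))
    return cq.simulate_hic(
        cq.HicSimSpec(
            n_bins=500,
            tad_boundaries=bounds,
            tad_enrichment=3.0,
            depth=300.0,
            seed=5,
        )
    )
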