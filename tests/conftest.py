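import numpy as np
import pandas as pd
import pytest

from localqtl.datatypes import MarkerMap
from localqtl.simulate import simulate_study


@pytest.fixture(scope="session")
def tiny_map() -> MarkerMap:
    """Two chromosomes, 10 markers each, 50 kb spacing."""
    rows = [
        (f"SNP_{c}_{i + 1}", c, (i + 1) * 50_000)
        for c in (1, 2)
        for i in range(10)
    ]
    return MarkerMap(pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"]))


@pytest.fixture(scope="session")
def small_study():
    """Desk-scale population: 160 animals, 2 chr x 100 markers, 10 QTL."""
    return simulate_study(
        seed=42,
        n_founders=40,
        n_generations=3,
        n_chromosomes=2,
        markers_per_chromosome=100,
        qtl_spacing=20,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
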