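import numpy as np
import pandas as pd
import pytest

from fatmap.datatypes import GenotypeMatrix, MarkerMap
from fatmap.sim import SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_population():
    """A modest synthetic population shared by read-only tests."""
    cfg = SimConfig(seed=11, n_markers=400, n_chromosomes=3, n_qtl=4,
                    offspring_per_dam=6)
    return simulate_population(cfg)


@pytest.fixture()
def toy_map():
    return MarkerMap(pd.DataFrame({
        "marker_id": ["m1", "m2", "m3"],
        "chromosome": ["1", "1", "2"],
        "position_bp": [100, 1_500_000, 50],
        "ref_allele": ["A", "C", "G"],
        "alt_allele": ["G", "T", "A"],
    }))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_genotypes(rng, n, k, freqs=None, missing_rate=0.0):
    freqs = freqs if freqs is not None else rng.uniform(0.1, 0.9, k)
    dose = rng.binomial(2, freqs, size=(n, k)).astype(float)
    if missing_rate:
        mask = rng.random((n, k)) < missing_rate
        dose[mask] = np.nan
    ids = np.array([f"a{i}" for i in range(n)], dtype=object)
    return GenotypeMatrix(ids, dose)
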