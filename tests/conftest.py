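import numpy as np
import pytest

from megafactor.io_formats import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genotypes(rng):
    """5 x 10 random genotype matrix with a couple of missing cells."""
    dos = rng.integers(0, 3, size=(5, 10)).astype(float)
    dos[0, 3] = np.nan
    dos[4, 7] = np.nan
    return GenotypeMatrix(
        dosages=dos,
        sample_ids=np.array([f"s{i}" for i in range(5)], dtype=object),
        marker_ids=np.array([f"m{j}" for j in range(10)], dtype=object),
        chromosome=np.repeat("1", 10),
        position_bp=np.arange(1, 11) * 100,
    )
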