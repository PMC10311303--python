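import numpy as np
import pytest

from lcrcall.aggregate import GenotypingParams


@pytest.fixture
def params() -> GenotypingParams:
    return GenotypingParams(epsilon=0.01, mean_read_len=150.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_site_instance(rng, max_alleles=3, max_agcn=6):
    """A random small genotyping instance (alleles, depths, agcn)."""
    bases = ["A", "C", "G", "T", "AT", "ATG"]
    n_alleles = int(rng.integers(1, max_alleles + 1))
    alleles = sorted(
        rng.choice(bases, size=n_alleles, replace=False).tolist(),
        key=lambda a: (len(a), a),
    )
    agcn = int(rng.integers(1, max_agcn + 1))
    depths = rng.integers(0, 40, size=len(alleles)).tolist()
    return alleles, depths, agcn
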