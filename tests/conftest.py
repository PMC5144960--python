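import numpy as np
import pytest

from dopop.genome import DriveLocus, GenomeMap


@pytest.fixture(scope="session")
def small_map() -> GenomeMap:
    """Two autosomes plus X: enough to cover the drive locus and the PAR."""
    return GenomeMap.default(n_autosomes=2, markers_per_chrom=50)


@pytest.fixture(scope="session")
def locus() -> DriveLocus:
    return DriveLocus()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160929)
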