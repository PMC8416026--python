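import numpy as np
import pytest
import scipy.sparse as sp

from mitoscale.genome_io import ContactMatrix, GenomicBinning


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def small_binning():
    return GenomicBinning.from_dict({"chr1": 60_000, "chr2": 35_000}, 10_000)


def random_matrix(n_bins=30, chrom_len=None, bin_width=10_000, seed=0, density=0.6):
    """A random symmetric single-chromosome ContactMatrix for unit tests."""
    rng = np.random.default_rng(seed)
    chrom_len = chrom_len or n_bins * bin_width
    binning = GenomicBinning.from_dict({"chrT": chrom_len}, bin_width)
    n = binning.n_bins("chrT")
    dense = rng.poisson(8, size=(n, n)) * (rng.random((n, n)) < density)
    upper = np.triu(dense)
    return ContactMatrix(binning, {"chrT": sp.csr_matrix(upper.astype(float))})


@pytest.fixture
def toy_matrix():
    return random_matrix(n_bins=30, seed=42)
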