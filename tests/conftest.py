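import numpy as np
import pytest

from tiledc import BinGrid, ContactMatrix, GenomicInterval


@pytest.fixture
def grid10():
    """Tiny 10-bin grid at 2 kb resolution."""
    return BinGrid(GenomicInterval("chrT", 0, 20_000), 2000)


@pytest.fixture
def tile_grid():
    """The 1268-bin preset tile geometry."""
    return BinGrid(
        GenomicInterval.from_inclusive("chr16", 91_566_000, 94_101_999), 2000
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_raw_matrix(grid, rng, mean=5.0):
    """Dense-support random raw count matrix on a grid."""
    n = grid.n_bins
    iu, ju = np.triu_indices(n)
    counts = rng.poisson(mean, size=iu.size)
    return ContactMatrix(grid, iu, ju, counts.astype(float), stage="raw")
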