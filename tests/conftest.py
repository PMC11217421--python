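import numpy as np
import pytest

from perichrom.genome import GenomeLayout, GenomicInterval, IntervalSet


@pytest.fixture
def layout():
    return GenomeLayout(("chrA", "chrB"), (100_000, 60_000))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_intervals(rng, layout, n, max_len=2000):
    """Random valid intervals on a layout (may overlap)."""
    ivs = []
    chroms = list(layout.chrom_names)
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        L = layout.length_of(chrom)
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, L - length))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(ivs, layout=layout)
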