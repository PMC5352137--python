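import numpy as np
import pytest

from cooccupy.core import GenomeLayout, GenomicInterval, PeakSet


@pytest.fixture
def genome():
    return GenomeLayout.from_lengths([1_000_000, 500_000])


def random_peakset(rng, genome, n, label="x", max_len=500, scored=False):
    """Random (possibly overlapping) intervals on a genome — shared helper
    for the oracle-equivalence tests."""
    ivs = []
    for i in range(n):
        chrom, length = genome.chromosomes[rng.integers(len(genome.chromosomes))]
        start = int(rng.integers(0, length - max_len - 1))
        end = start + int(rng.integers(1, max_len))
        score = float(rng.integers(1, 100)) if scored else None
        ivs.append(GenomicInterval(chrom, start, end, f"{label}{i}", score))
    return PeakSet(label, genome, ivs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
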