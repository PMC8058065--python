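import numpy as np
import pytest

from enhancerome.intervals import GenomeLayout, GenomicInterval, IntervalSet
from enhancerome.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def toy_genome() -> GenomeLayout:
    return GenomeLayout({"chr1": 10_000, "chr2": 8_000})


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort, shared across the session."""
    return simulate_cohort(CohortConfig(rng_seed=11))


def random_interval_set(
    rng: np.random.Generator, genome: GenomeLayout, n: int, max_len: int = 500
) -> IntervalSet:
    ivs = []
    chroms = list(genome.chromosomes)
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        L = genome.length(chrom)
        length = int(rng.integers(1, min(max_len, L) + 1))
        start = int(rng.integers(0, L - length + 1))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(ivs)
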