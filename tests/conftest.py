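import numpy as np
import pytest

from k4balance.genome_intervals import GenomeLayout, Interval, IntervalSet


@pytest.fixture
def small_genome():
    return GenomeLayout([("chr1", 1000), ("chr2", 1000)])


@pytest.fixture
def toy_genome():
    """The default simulation scale: 2 chromosomes x 500 kb."""
    return GenomeLayout([("chr1", 500_000), ("chr2", 500_000)])


def ivset(genome, triples):
    return IntervalSet([Interval(c, s, e) for c, s, e in triples], genome)


def basemask(ivs: IntervalSet) -> dict[str, np.ndarray]:
    """Per-base boolean-occupancy oracle for interval set algebra."""
    masks = {c: np.zeros(l, dtype=bool) for c, l in ivs.genome.chromosomes}
    for iv in ivs:
        masks[iv.chrom][iv.start:iv.end] = True
    return masks


def random_ivset(genome, rng, max_n=12, max_len=120) -> IntervalSet:
    out = []
    for _ in range(rng.integers(1, max_n + 1)):
        chrom, length = genome.chromosomes[rng.integers(len(genome.chromosomes))]
        l = int(rng.integers(1, min(max_len, length) + 1))
        s = int(rng.integers(0, length - l + 1))
        out.append(Interval(chrom, s, s + l))
    return IntervalSet(out, genome)
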