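import numpy as np
import pytest

from regloop.genomics_core import GenomeLayout, GenomicInterval, GeneModel, PeakSet


@pytest.fixture
def small_genome():
    return GenomeLayout([("chr1", 100_000), ("chr2", 80_000)])


@pytest.fixture
def three_genes():
    """Two genes on chr1 (one per strand) and one on chr2."""
    return [
        GeneModel("gA", GenomicInterval("chr1", 5_000, 6_000), "+"),
        GeneModel("gB", GenomicInterval("chr1", 20_000, 25_000), "-"),
        GeneModel("gC", GenomicInterval("chr2", 10_000, 12_000), "+"),
    ]


def random_disjoint_intervals(rng, chroms, max_n=50, genome_len=10_000):
    """Random sorted disjoint intervals for oracle comparisons."""
    out = []
    for chrom in chroms:
        n = int(rng.integers(0, max_n + 1))
        cuts = np.sort(rng.choice(genome_len, size=min(2 * n, genome_len), replace=False))
        for s, e in zip(cuts[0::2], cuts[1::2]):
            if e > s:
                out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def mask_of(intervals, chroms, genome_len=10_000):
    """Per-basepair boolean-mask oracle of an interval collection."""
    masks = {c: np.zeros(genome_len, dtype=bool) for c in chroms}
    for iv in intervals:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks
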