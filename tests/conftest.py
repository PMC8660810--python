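"""Shared fixtures: small synthetic worlds and hand-built toy annotations."""

import numpy as np
import pytest

from crossoccupy import GeneModel, GenomicInterval, Peak, WorldConfig, make_world


@pytest.fixture(scope="session")
def world():
    """Default synthetic world: 500 peaks/condition, shared fraction 0.4."""
    return make_world(seed=17)


@pytest.fixture(scope="session")
def small_world():
    """A quick world for I/O and closure smoke tests."""
    cfg = WorldConfig(n_peaks=60, n_genes=10, n_extra_accessible=20)
    return make_world(cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_peak(chrom, start, end, summit=None, name="", score=0.0, zscore=None):
    iv = GenomicInterval(chrom=chrom, start=start, end=end, name=name)
    if summit is None:
        summit = (start + end) // 2
    return Peak(interval=iv, summit=summit, score=score, zscore=zscore)


@pytest.fixture(scope="session")
def toy_genes():
    """Three hand-placed genes on one chromosome for annotation tests.

    geneA: + strand, [10_000, 14_000), TSS 10_000; exons [10000,10400) and
           [13600,14000); 5'UTR first 150 bp, 3'UTR last 150 bp.
    geneB: - strand, [20_000, 26_000), TSS 25_999.
    geneC: + strand, [40_000, 42_000), TSS 40_000.
    """

    def gene(gene_id, strand, start, end):
        exon1 = GenomicInterval(chrom="chrT", start=start, end=start + 400, strand=strand)
        exon2 = GenomicInterval(chrom="chrT", start=end - 400, end=end, strand=strand)
        if strand == "+":
            utr5 = [GenomicInterval(chrom="chrT", start=start, end=start + 150, strand=strand)]
            utr3 = [GenomicInterval(chrom="chrT", start=end - 150, end=end, strand=strand)]
        else:
            utr5 = [GenomicInterval(chrom="chrT", start=end - 150, end=end, strand=strand)]
            utr3 = [GenomicInterval(chrom="chrT", start=start, end=start + 150, strand=strand)]
        return GeneModel(
            gene_id=gene_id, chrom="chrT", strand=strand, start=start, end=end,
            exons=[exon1, exon2], utr5=utr5, utr3=utr3,
        )

    return [gene("geneA", "+", 10_000, 14_000), gene("geneB", "-", 20_000, 26_000),
            gene("geneC", "+", 40_000, 42_000)]
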