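import numpy as np
import pytest

from erosure.io_formats import GenotypeMatrix, Impact


def make_gm(
    genotypes,
    pos=None,
    chrom=None,
    populations=None,
    years=None,
    impact=None,
    ancestral_is_ref=None,
    sample_ids=None,
):
    """Build a small GenotypeMatrix with sensible defaults for tests."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    if chrom is None:
        chrom = np.array(["chr1"] * m, dtype=object)
    if populations is None:
        populations = np.array(["P1"] * n, dtype=object)
    if years is None:
        years = np.full(n, 2000)
    if impact is None:
        impact = np.full(m, int(Impact.UNANNOTATED), dtype=np.int8)
    if ancestral_is_ref is None:
        ancestral_is_ref = np.ones(m, dtype=bool)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(
        sample_ids=sample_ids,
        populations=np.asarray(populations, dtype=object),
        years=np.asarray(years),
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos),
        genotypes=g,
        ancestral_is_ref=np.asarray(ancestral_is_ref, dtype=bool),
        impact=np.asarray(impact, dtype=np.int8),
    )


@pytest.fixture
def gm_factory():
    return make_gm
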