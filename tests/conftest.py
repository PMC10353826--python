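import numpy as np
import pytest

from selfingpop.genotype import GenotypeMatrix


def make_matrix(calls, pos=None, chrom="chr1", sample_ids=None):
    """Small-genotype-matrix builder used across the suite."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 10
    if sample_ids is None:
        sample_ids = [f"s{i:02d}" for i in range(n)]
    return GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.array([chrom] * m, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref_allele=np.array(["A"] * m, dtype=object),
        alt_allele=np.array(["T"] * m, dtype=object),
        calls=calls,
    )


@pytest.fixture
def matrix_builder():
    return make_matrix
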