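import numpy as np
import pytest

from balsel.io_formats import MaskSet, VariantTable
from balsel.popgen_core import HaplotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20230525)


@pytest.fixture
def empty_masks():
    return MaskSet()


def random_hapmatrix(rng, n_hap=8, n_sites=20, span=2000) -> HaplotypeMatrix:
    """Random polymorphic matrix (columns forced segregating)."""
    m = rng.integers(0, 2, size=(n_hap, n_sites), dtype=np.uint8)
    for j in range(n_sites):
        if m[:, j].sum() in (0, n_hap):
            m[rng.integers(n_hap), j] ^= 1
            m[(rng.integers(n_hap)), j] ^= 0
            if m[:, j].sum() in (0, n_hap):
                m[0, j] = 0
                m[1, j] = 1
    pos = np.sort(rng.choice(span, size=n_sites, replace=False))
    return HaplotypeMatrix(m, pos)


def make_variant_table(matrix, positions1, contig="chr1") -> VariantTable:
    matrix = np.asarray(matrix, dtype=np.uint8)
    n_hap = matrix.shape[0]
    samples = []
    for i in range(n_hap // 2):
        samples.extend([f"s{i + 1}_1", f"s{i + 1}_2"])
    m = matrix.shape[1]
    return VariantTable(
        contig=contig,
        positions=np.asarray(positions1, dtype=np.int64),
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["G"] * m, dtype=object),
        genotypes=matrix,
        sample_ids=samples,
    )
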