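import numpy as np
import pytest

from wildcore import GenotypeMatrix, LocusMeta, MISSING


def make_matrix(rows, ids=None, populations=None, loci=None):
    """Build a GenotypeMatrix from a list of dosage rows (None = missing)."""
    calls = np.array(
        [[MISSING if v is None else v for v in row] for row in rows], dtype=np.int8
    )
    n, l = calls.shape
    if ids is None:
        ids = [f"acc{i+1}" for i in range(n)]
    if loci is None:
        loci = [LocusMeta(f"L{j+1}", "1", j + 1, "A", "G") for j in range(l)]
    return GenotypeMatrix(list(ids), loci, calls, populations)


@pytest.fixture
def toy_matrix():
    """4 accessions x 3 loci with one missing call and mixed MAF."""
    return make_matrix(
        [
            [0, 1, 2],
            [0, 1, 0],
            [0, None, 1],
            [0, 2, 1],
        ]
    )


def random_matrix(rng, n=10, l=20, missing_rate=0.1, populations=None):
    calls = rng.integers(0, 3, size=(n, l)).astype(np.int8)
    if missing_rate:
        calls[rng.random((n, l)) < missing_rate] = MISSING
    return make_matrix(calls.tolist(), populations=populations)
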