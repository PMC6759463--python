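import numpy as np
import pytest

from lenspop.io import MISSING, GenotypeMatrix


@pytest.fixture
def tiny_matrix() -> GenotypeMatrix:
    """Four samples x five loci with one missing call and known alleles."""
    calls = np.array(
        [
            [0, 1, 2, 0, 2],
            [0, 1, 2, 1, 2],
            [2, 1, 0, MISSING, 0],
            [2, 1, 0, 2, 0],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        ["s1", "s2", "s3", "s4"],
        ["L1", "L2", "L3", "L4", "L5"],
        calls,
        [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T")],
    )


def fixed_difference_matrix(n_per_group: int = 20, n_loci: int = 5):
    """Two groups fixed for alternative alleles at every locus."""
    calls = np.vstack(
        [np.full((n_per_group, n_loci), 2), np.full((n_per_group, n_loci), 0)]
    ).astype(np.int8)
    ids = [f"a{i}" for i in range(n_per_group)] + [f"b{i}" for i in range(n_per_group)]
    g = GenotypeMatrix(ids, [f"L{j}" for j in range(n_loci)], calls,
                       [("A", "G")] * n_loci)
    labels = ["A"] * n_per_group + ["B"] * n_per_group
    return g, labels
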