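import numpy as np
import pytest

from synteloss import OrthogroupMatrix, RootedTree


@pytest.fixture
def quartet_tree() -> RootedTree:
    return RootedTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


def matrix_from_presence(og_presence: dict[str, list[str]], taxa: list[str]) -> OrthogroupMatrix:
    """Build a 0/1 orthogroup matrix from {og: [present taxa]}."""
    og_ids = list(og_presence)
    counts = np.zeros((len(og_ids), len(taxa)), dtype=np.int64)
    for i, og in enumerate(og_ids):
        for t in og_presence[og]:
            counts[i, taxa.index(t)] = 1
    return OrthogroupMatrix(og_ids, taxa, counts=counts)


@pytest.fixture
def matrix_builder():
    return matrix_from_presence
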