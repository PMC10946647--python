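import numpy as np
import pytest

from phyloppc.simulate import Alignment
from phyloppc.trees import PhyloTree


@pytest.fixture
def rng():
    return np.random.default_rng(20240304)


def make_three_taxon_tree(lengths=(0.1, 0.1, 0.1)):
    """Star tree on three leaves A, B, C (the smallest valid unrooted
    tree)."""
    parent = np.array([3, 3, 3, -1], dtype=np.int32)
    childmat = np.full((4, 3), -1, dtype=np.int32)
    childmat[3] = [0, 1, 2]
    nchild = np.array([0, 0, 0, 3], dtype=np.int32)
    lens = np.array([*lengths, np.nan])
    return PhyloTree(["A", "B", "C"], parent, childmat, nchild, lens, 3)


def make_four_taxon_tree(internal=0.1, terminal=0.1, labels=None):
    """The 4-leaf tree ((A,B),(C,D)) with the given branch lengths."""
    if labels is None:
        labels = ["A", "B", "C", "D"]
    # nodes: 0..3 leaves, 4 root (children 0, 1, 5), 5 internal (2, 3)
    parent = np.array([4, 4, 5, 5, -1, 4], dtype=np.int32)
    childmat = np.full((6, 3), -1, dtype=np.int32)
    childmat[4] = [0, 1, 5]
    childmat[5, :2] = [2, 3]
    nchild = np.array([0, 0, 0, 0, 3, 2], dtype=np.int32)
    lens = np.array([terminal, terminal, terminal, terminal, np.nan,
                     internal])
    return PhyloTree(labels, parent, childmat, nchild, lens, 4)


def alignment_from_columns(columns, taxa=None):
    """Alignment built from a list of site columns (strings)."""
    n_taxa = len(columns[0])
    if taxa is None:
        taxa = [f"t{i + 1}" for i in range(n_taxa)]
    seqs = ["".join(col[i] for col in columns) for i in range(n_taxa)]
    return Alignment.from_sequences(taxa, seqs)


@pytest.fixture
def three_taxon_tree():
    return make_three_taxon_tree()


@pytest.fixture
def four_taxon_tree():
    return make_four_taxon_tree()
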