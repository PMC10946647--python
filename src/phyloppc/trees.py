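"""Unrooted phylogenetic trees with node-attached branch lengths.

Trees are stored in flat arrays for speed.  The unrooted topology is
represented rooted at an arbitrary internal node of degree 3 (the
"virtual root"); every other internal node has exactly two children.
Each non-root node carries the length of the edge above it.  All
substitution models used here are time-reversible, so the likelihood is
invariant to the placement of the virtual root (pulley principle).

For ``n`` leaves there are ``2n - 2`` nodes (leaves ``0 .. n-1``,
internals ``n .. 2n-3``) and ``2n - 3`` edges.
"""

from __future__ import annotations

import io

import numpy as np

__all__ = ["PhyloTree", "sample_topology", "sample_branch_lengths"]


class PhyloTree:
    """Unrooted labelled binary tree plus branch lengths.

    Attributes
    ----------
    taxa : list of str
        Leaf labels; leaf node ``i`` carries ``taxa[i]``.
    parent : int array, shape (n_nodes,)
        Parent of each node; ``-1`` for the virtual root.
    childmat : int array, shape (n_nodes, 3)
        Children, padded with ``-1``; only the root uses all 3 slots.
    nchild : int array, shape (n_nodes,)
    lengths : float array, shape (n_nodes,)
        Length of the edge above each node; NaN at the root.
    root : int
        Index of the virtual root (an internal node).
    """

    __slots__ = ("taxa", "parent", "childmat", "nchild", "lengths", "root")

    def __init__(self, taxa, parent, childmat, nchild, lengths, root):
        self.taxa = list(taxa)
        self.parent = np.asarray(parent, dtype=np.int32)
        self.childmat = np.asarray(childmat, dtype=np.int32)
        self.nchild = np.asarray(nchild, dtype=np.int32)
        self.lengths = np.asarray(lengths, dtype=np.float64)
        self.root = int(root)

    # ------------------------------------------------------------------
    # basic queries
    # ------------------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_taxa - 2

    @property
    def n_edges(self) -> int:
        return 2 * self.n_taxa - 3

    def edge_nodes(self) -> np.ndarray:
        """Indices of all non-root nodes, i.e. one per edge."""
        return np.array([v for v in range(self.n_nodes) if v != self.root],
                        dtype=np.int32)

    def tree_length(self) -> float:
        """Sum of all branch lengths."""
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.root] = False
        return float(self.lengths[mask].sum())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.taxa, self.parent.copy(), self.childmat.copy(),
                         self.nchild.copy(), self.lengths.copy(), self.root)

    def postorder_internal(self) -> np.ndarray:
        """Internal nodes in postorder (children before parents, root last)."""
        n_taxa = self.n_taxa
        order = []
        stack = [self.root]
        seen = []
        while stack:
            v = stack.pop()
            seen.append(v)
            for i in range(self.nchild[v]):
                c = self.childmat[v, i]
                if c >= n_taxa:
                    stack.append(c)
        for v in reversed(seen):
            order.append(v)
        return np.asarray(order, dtype=np.int32)

    def subtree_nodes(self, v: int) -> list:
        """All nodes in the subtree rooted at ``v`` (including ``v``)."""
        out = [v]
        stack = [v]
        n_taxa = self.n_taxa
        while stack:
            u = stack.pop()
            for i in range(self.nchild[u]):
                c = self.childmat[u, i]
                out.append(c)
                if c >= n_taxa:
                    stack.append(c)
        # leaves appended but never expanded; fix ordering irrelevant
        return out

    def validate(self) -> None:
        """Raise ``ValueError`` if the structural invariants are broken."""
        n = self.n_taxa
        if n < 3:
            raise ValueError("tree needs at least 3 leaves")
        if self.nchild[self.root] != 3:
            raise ValueError("virtual root must have degree 3")
        for v in range(self.n_nodes):
            if v < n and self.nchild[v] != 0:
                raise ValueError(f"leaf {v} has children")
            if v >= n and v != self.root and self.nchild[v] != 2:
                raise ValueError(f"internal node {v} is not binary")
            for i in range(self.nchild[v]):
                c = self.childmat[v, i]
                if self.parent[c] != v:
                    raise ValueError(f"parent/child mismatch at {v}->{c}")
        lens = np.delete(self.lengths, self.root)
        if np.any(~np.isnan(lens) & (lens <= 0)):
            raise ValueError("branch lengths must be strictly positive")
        if len(set(self.taxa)) != n:
            raise ValueError("leaf labels must be unique")

    # ------------------------------------------------------------------
    # topology identity
    # ------------------------------------------------------------------
    def bipartitions(self) -> frozenset:
        """Nontrivial bipartitions as leaf bitmasks.

        Each internal edge splits the leaves in two; the split is encoded
        as the bitmask of the side *not* containing leaf 0, so the
        encoding does not depend on the virtual-root placement.
        """
        n = self.n_taxa
        full = (1 << n) - 1
        mask = np.zeros(self.n_nodes, dtype=object)
        for v in range(n):
            mask[v] = 1 << v
        splits = []
        for v in self.postorder_internal():
            m = 0
            for i in range(self.nchild[v]):
                m |= mask[self.childmat[v, i]]
            mask[v] = m
            if v != self.root:
                if m & 1:
                    m = full & ~m
                # leaf edges and the root give trivial splits
                bc = bin(m).count("1")
                if 2 <= bc <= n - 2:
                    splits.append(m)
        return frozenset(splits)

    def topology_key(self) -> frozenset:
        """Hashable identifier of the unrooted topology."""
        return self.bipartitions()

    # ------------------------------------------------------------------
    # re-rooting (representation change only)
    # ------------------------------------------------------------------
    def reroot(self, new_root: int) -> None:
        """Move the virtual root to internal node ``new_root`` in place.

        Pure representation change: the unrooted topology and the
        multiset of branch lengths are untouched.
        """
        if new_root == self.root:
            return
        if new_root < self.n_taxa:
            raise ValueError("virtual root must be an internal node")
        path = [new_root]
        while path[-1] != self.root:
            path.append(int(self.parent[path[-1]]))
        old_len = self.lengths.copy()
        # reverse parent/child orientation along the path
        for a, b in zip(path[:-1], path[1:]):
            # b was parent of a; now a becomes parent of b
            row = self.childmat[b]
            for i in range(self.nchild[b]):
                if row[i] == a:
                    row[i] = row[self.nchild[b] - 1]
                    row[self.nchild[b] - 1] = -1
                    break
            self.nchild[b] -= 1
            self.childmat[a, self.nchild[a]] = b
            self.nchild[a] += 1
            self.parent[b] = a
            self.lengths[b] = old_len[a]
        self.parent[new_root] = -1
        self.lengths[new_root] = np.nan
        self.root = new_root

    # ------------------------------------------------------------------
    # Newick I/O
    # ------------------------------------------------------------------
    def newick(self, digits: int = 12) -> str:
        """Newick string with branch lengths at ``digits`` significant
        digits (default 12)."""
        fmt = "%%.%dg" % digits

        def sub(v):
            if v < self.n_taxa:
                lab = self.taxa[v]
            else:
                lab = "(%s)" % ",".join(
                    sub(self.childmat[v, i]) for i in range(self.nchild[v]))
            return "%s:%s" % (lab, fmt % self.lengths[v])

        inner = ",".join(sub(self.childmat[self.root, i])
                         for i in range(self.nchild[self.root]))
        return "(%s);" % inner

    @classmethod
    def from_newick(cls, source: str) -> "PhyloTree":
        """Parse a Newick string (or text of one tree) into a
        :class:`PhyloTree`.

        The tree must be binary; a bifurcating root is suppressed so the
        result is always in unrooted (degree-3 root) form.
        """
        import dendropy

        try:
            dtree = dendropy.Tree.get(
                data=source, schema="newick",
                suppress_internal_node_taxa=True)
        except Exception as exc:  # dendropy errors carry line info
            raise ValueError(f"malformed newick: {exc}") from exc
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree) -> "PhyloTree":
        dtree = dtree.clone(depth=1)
        if len(dtree.seed_node.child_nodes()) == 2:
            dtree.deroot()
        leaves = [lf for lf in dtree.leaf_node_iter()]
        taxa = [lf.taxon.label for lf in leaves]
        n = len(taxa)
        if n < 3:
            raise ValueError("tree needs at least 3 leaves")
        n_nodes = 2 * n - 2
        parent = np.full(n_nodes, -1, dtype=np.int32)
        childmat = np.full((n_nodes, 3), -1, dtype=np.int32)
        nchild = np.zeros(n_nodes, dtype=np.int32)
        lengths = np.full(n_nodes, np.nan)
        ids = {}
        for i, lf in enumerate(leaves):
            ids[id(lf)] = i
        nxt = n
        for nd in dtree.preorder_node_iter():
            if nd.is_leaf():
                continue
            ids[id(nd)] = nxt
            nxt += 1
        if nxt != n_nodes:
            raise ValueError("tree is not strictly binary")
        root = ids[id(dtree.seed_node)]
        for nd in dtree.preorder_node_iter():
            v = ids[id(nd)]
            if nd.parent_node is not None:
                p = ids[id(nd.parent_node)]
                parent[v] = p
                childmat[p, nchild[p]] = v
                nchild[p] += 1
                lengths[v] = (nd.edge.length
                              if nd.edge.length is not None else np.nan)
        tree = cls(taxa, parent, childmat, nchild, lengths, root)
        tree.validate()
        return tree

    def to_dendropy(self, taxon_namespace=None):
        """Convert to a :class:`dendropy.Tree` (e.g. for RF oracles)."""
        import dendropy

        return dendropy.Tree.get(
            data=self.newick(), schema="newick",
            taxon_namespace=taxon_namespace)

    def __repr__(self):
        return f"<PhyloTree n_taxa={self.n_taxa}>"


def sample_topology(n_taxa: int, rng: np.random.Generator,
                    labels=None) -> PhyloTree:
    """Draw a uniform random unrooted labelled binary topology.

    Sequential random addition: start from the unique 3-leaf tree and
    attach each further leaf to an edge chosen uniformly at random.  Each
    of the ``(2n-5)!!`` topologies arises with equal probability.
    Branch lengths are left unset (NaN).
    """
    if n_taxa < 4:
        raise ValueError(f"need at least 4 taxa, got {n_taxa}")
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_taxa)]
    elif len(labels) != n_taxa:
        raise ValueError("labels length must equal n_taxa")
    n_nodes = 2 * n_taxa - 2
    parent = np.full(n_nodes, -1, dtype=np.int32)
    childmat = np.full((n_nodes, 3), -1, dtype=np.int32)
    nchild = np.zeros(n_nodes, dtype=np.int32)
    lengths = np.full(n_nodes, np.nan)
    root = n_taxa
    for i in range(3):
        childmat[root, i] = i
        parent[i] = root
    nchild[root] = 3
    # nodes present so far, excluding the root: candidate attachment edges
    attachable = [0, 1, 2]
    next_internal = n_taxa + 1
    for k in range(3, n_taxa):
        v = attachable[rng.integers(len(attachable))]
        m = next_internal
        next_internal += 1
        p = parent[v]
        row = childmat[p]
        row[np.argmax(row[: nchild[p]] == v)] = m
        parent[m] = p
        childmat[m, 0] = v
        childmat[m, 1] = k
        nchild[m] = 2
        parent[v] = m
        parent[k] = m
        attachable.extend([m, k])
    return PhyloTree(labels, parent, childmat, nchild, lengths, root)


def sample_branch_lengths(topology: PhyloTree, bl_rate: float,
                          rng: np.random.Generator) -> PhyloTree:
    """Attach i.i.d. Exponential(``bl_rate``) branch lengths to every
    edge of ``topology`` (returned as a new tree)."""
    if bl_rate <= 0:
        raise ValueError("bl_rate must be positive")
    tree = topology.copy()
    draws = rng.exponential(1.0 / bl_rate, size=tree.n_nodes)
    tree.lengths[:] = draws
    tree.lengths[tree.root] = np.nan
    return tree
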