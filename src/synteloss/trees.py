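"""Rooted species trees: Newick I/O, MRCA queries, rerooting, bipartitions.

Newick parsing and rerooting are delegated to :mod:`dendropy`; this module
adds a flat, index-based view of the rooted topology that the Dollo
reconstruction can traverse cheaply, plus the validation the analyses need
(unique tip names, taxon/tip agreement).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = ["RootedTree", "load_tree", "reroot", "TreeError"]


class TreeError(ValueError):
    """Raised for malformed trees or invalid tree queries."""


class RootedTree:
    """A rooted (possibly multifurcating) tree with labelled tips.

    Nodes are indexed 0..n-1 in preorder with the root at index 0.  Tip
    labels come from the Newick taxa; internal nodes keep their Newick
    label when present and otherwise get a deterministic ``N<i>`` label.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._dtree = dtree
        nodes = list(dtree.preorder_node_iter())
        self._n = len(nodes)
        index = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent: list[int] = [-1] * self._n
        self.children: list[list[int]] = [[] for _ in range(self._n)]
        self.labels: list[str] = [""] * self._n
        self.branch_lengths: list[float | None] = [None] * self._n
        self.tip_index: dict[str, int] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
            self.branch_lengths[i] = nd.edge.length
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeError("tree has an unlabelled tip")
                label = nd.taxon.label
                if label in self.tip_index:
                    raise TreeError(f"duplicate tip label: {label!r}")
                self.tip_index[label] = i
            else:
                label = nd.label if nd.label else f"N{i}"
            self.labels[i] = label
        # tips below each node, as frozensets of tip names (postorder fill)
        below: list[set[str]] = [set() for _ in range(self._n)]
        for i in range(self._n - 1, -1, -1):
            if not self.children[i]:
                below[i].add(self.labels[i])
            for c in self.children[i]:
                below[i] |= below[c]
        self.tips_below: list[frozenset[str]] = [frozenset(s) for s in below]
        self._depth = [0] * self._n
        for i in range(1, self._n):
            self._depth[i] = self._depth[self.parent[i]] + 1

    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "RootedTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse errors
            raise TreeError(f"unreadable Newick: {exc}") from exc
        dtree.is_rooted = True
        return cls(dtree)

    @classmethod
    def from_file(cls, path) -> "RootedTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self._dtree.as_string(schema="newick", suppress_rooting=True).strip()

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self._n

    @property
    def root(self) -> int:
        return 0

    @property
    def tips(self) -> frozenset[str]:
        return self.tips_below[0]

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    def preorder(self) -> Iterator[int]:
        return iter(range(self._n))

    def postorder(self) -> Iterator[int]:
        return iter(range(self._n - 1, -1, -1))

    def branch_length(self, i: int, default: float = 1.0) -> float:
        """Length of the edge above node ``i`` (``default`` when absent)."""
        bl = self.branch_lengths[i]
        return default if bl is None else bl

    def has_branch_lengths(self) -> bool:
        return all(self.branch_lengths[i] is not None for i in range(1, self._n))

    def mrca(self, taxa: Iterable[str]) -> int:
        """Most recent common ancestor (node index) of a set of tip names."""
        taxa = list(taxa)
        if not taxa:
            raise TreeError("MRCA of an empty taxon set is undefined")
        unknown = [t for t in taxa if t not in self.tip_index]
        if unknown:
            raise TreeError(f"taxa not in tree: {sorted(unknown)}")
        node = self.tip_index[taxa[0]]
        for t in taxa[1:]:
            other = self.tip_index[t]
            while self._depth[node] > self._depth[other]:
                node = self.parent[node]
            while self._depth[other] > self._depth[node]:
                other = self.parent[other]
            while node != other:
                node = self.parent[node]
                other = self.parent[other]
        return node

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Non-trivial unrooted bipartitions, each as a 2-set of tip-name sets."""
        out: set[frozenset[frozenset[str]]] = set()
        all_tips = self.tips
        for i in range(1, self._n):
            side = self.tips_below[i]
            if 1 < len(side) < len(all_tips) - 1:
                out.add(frozenset({side, all_tips - side}))
        return out

    def reroot(self, outgroup: Iterable[str]) -> "RootedTree":
        """Reroot so the given outgroup taxa form one side of the root.

        The outgroup must be a proper nonempty subset of the tips; rerooting
        preserves the tip set and every unrooted bipartition.
        """
        og = set(outgroup)
        if not og:
            raise TreeError("empty outgroup")
        missing = og - self.tips
        if missing:
            raise TreeError(f"outgroup taxa not in tree: {sorted(missing)}")
        if og == set(self.tips):
            raise TreeError("outgroup cannot contain every tip")
        dtree = self._dtree.clone(depth=1)
        mrca = dtree.mrca(taxon_labels=sorted(og))
        if mrca is dtree.seed_node:
            # the outgroup spans the current root; reroot on the complement
            comp = set(self.tips) - og
            mrca = dtree.mrca(taxon_labels=sorted(comp))
            if mrca is dtree.seed_node:
                raise TreeError("outgroup is not a clade under any rooting")
        length = mrca.edge.length
        dtree.reroot_at_edge(
            mrca.edge,
            length1=None if length is None else length / 2.0,
            length2=None if length is None else length / 2.0,
        )
        dtree.suppress_unifurcations()
        return RootedTree(dtree)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RootedTree({len(self.tips)} tips, {self._n} nodes)"


def load_tree(path) -> RootedTree:
    """Read a rooted tree from a Newick file."""
    return RootedTree.from_file(path)


def reroot(tree: RootedTree, outgroup: Iterable[str]) -> RootedTree:
    return tree.reroot(outgroup)
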