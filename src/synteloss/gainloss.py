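"""Dollo-parsimony reconstruction of orthogroup origins and losses on a rooted tree.

Under Dollo parsimony a character (orthogroup presence) is gained exactly
once and can only be lost thereafter.  For a presence pattern the unique
minimal reconstruction places the origin at the MRCA of the present tips;
within that subtree, the loss edges are exactly the edges from a node whose
subtree retains the orthogroup to a child whose subtree does not.  Losses
are attributed to the child node of the loss edge.

Tip "gene gains" are reported under two definitions, both emitted:

* ``orthogroup_gains`` — orthogroups whose origin is the terminal edge;
* ``gene_gains`` — total member genes of those tip-born orthogroups, plus
  the copy-number excess (count - 1, summed) in older orthogroups still
  present at the tip, i.e. genes added by duplication since the tip's
  divergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DataWarning, OrthogroupMatrix
from .trees import RootedTree, TreeError

__all__ = [
    "GainLossSummary",
    "dollo_origin",
    "dollo_losses",
    "summarize_gain_loss",
    "topology_contrast",
]


def dollo_origin(tree: RootedTree, present_tips) -> int:
    """Node index of the single Dollo origin: the MRCA of the present tips."""
    tips = set(present_tips)
    if not tips:
        raise TreeError("cannot place the origin of an all-absent orthogroup")
    return tree.mrca(tips)


def dollo_losses(tree: RootedTree, present_tips) -> frozenset[int]:
    """Loss edges of the minimal single-gain explanation, as child node indices.

    Within the origin's subtree, a node is *retaining* iff its subtree holds
    at least one present tip; loss edges run from a retaining parent to a
    non-retaining child.
    """
    tips = set(present_tips)
    origin = dollo_origin(tree, tips)
    retaining = _retaining_mask(tree, tips)
    in_subtree = _subtree_mask(tree, origin)
    losses = [
        c
        for c in range(1, tree.n_nodes)
        if in_subtree[tree.parent[c]]
        and retaining[tree.parent[c]]
        and not retaining[c]
    ]
    return frozenset(losses)


def _retaining_mask(tree: RootedTree, tips: set[str]) -> np.ndarray:
    out = np.zeros(tree.n_nodes, dtype=bool)
    for i in tree.postorder():
        if tree.is_tip(i):
            out[i] = tree.labels[i] in tips
        else:
            out[i] = any(out[c] for c in tree.children[i])
    return out


def _subtree_mask(tree: RootedTree, node: int) -> np.ndarray:
    out = np.zeros(tree.n_nodes, dtype=bool)
    out[node] = True
    for i in range(node + 1, tree.n_nodes):
        if out[tree.parent[i]]:
            out[i] = True
    return out


@dataclass
class GainLossSummary:
    """Per-node origin/loss counts plus per-tip gene-gain tallies."""

    tree: RootedTree
    per_node: pd.DataFrame  # node, label, is_tip, n_origins, n_losses
    tip_gains: pd.DataFrame  # taxon, orthogroup_gains, gene_gains
    n_dropped_all_absent: int

    def by_clade(self) -> dict[frozenset[str], tuple[int, int]]:
        """(n_origins, n_losses) keyed by the clade's tip set — rotation-invariant."""
        out: dict[frozenset[str], tuple[int, int]] = {}
        for row in self.per_node.itertuples():
            out[self.tree.tips_below[row.node]] = (row.n_origins, row.n_losses)
        return out

    @property
    def total_origins(self) -> int:
        return int(self.per_node["n_origins"].sum())


def _presence_arrays(matrix: OrthogroupMatrix, tree: RootedTree):
    missing = [t for t in matrix.taxa if t not in tree.tip_index]
    if missing:
        raise TreeError(f"matrix taxa absent from tree: {sorted(missing)}")
    presence = matrix.presence()
    keep = presence.any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} orthogroup(s) absent from every analysis taxon",
            DataWarning,
        )
    return presence, keep, n_dropped


def summarize_gain_loss(
    matrix: OrthogroupMatrix, tree: RootedTree
) -> GainLossSummary:
    """Aggregate Dollo origins and losses over every orthogroup present in >=1 taxon."""
    presence, keep, n_dropped = _presence_arrays(matrix, tree)
    n_nodes = tree.n_nodes
    tip_cols = np.array([tree.tip_index[t] for t in matrix.taxa])
    depth = np.array([0] * n_nodes)
    for i in range(1, n_nodes):
        depth[i] = depth[tree.parent[i]] + 1

    # retaining[og, node]: subtree below node holds >=1 present analysis tip
    n_og = presence.shape[0]
    retaining = np.zeros((n_og, n_nodes), dtype=bool)
    retaining[:, tip_cols] = presence
    for i in tree.postorder():
        for c in tree.children[i]:
            retaining[:, i] |= retaining[:, c]

    # counts of present tips below each node -> origin = deepest node seeing all
    cnt = np.zeros((n_og, n_nodes), dtype=np.int32)
    cnt[:, tip_cols] = presence.astype(np.int32)
    for i in tree.postorder():
        for c in tree.children[i]:
            cnt[:, i] += cnt[:, c]
    total = presence.sum(axis=1).astype(np.int32)
    sees_all = cnt == total[:, None]
    origin = np.argmax(np.where(sees_all, depth[None, :], -1), axis=1)

    # ancestor[v, u]: u is an ancestor-or-self of v
    ancestor = np.zeros((n_nodes, n_nodes), dtype=bool)
    for v in range(n_nodes):
        u = v
        while u != -1:
            ancestor[v, u] = True
            u = tree.parent[u]

    n_origins = np.zeros(n_nodes, dtype=np.int64)
    n_losses = np.zeros(n_nodes, dtype=np.int64)
    kept_idx = np.flatnonzero(keep)
    np.add.at(n_origins, origin[kept_idx], 1)
    for c in range(1, n_nodes):
        p = tree.parent[c]
        is_loss = (
            keep
            & ~retaining[:, c]
            & retaining[:, p]
            & ancestor[p, origin]
        )
        n_losses[c] = int(is_loss.sum())

    per_node = pd.DataFrame(
        {
            "node": np.arange(n_nodes),
            "label": tree.labels,
            "is_tip": [tree.is_tip(i) for i in range(n_nodes)],
            "n_origins": n_origins,
            "n_losses": n_losses,
        }
    )

    # tip gains under both definitions
    rows = []
    counts = matrix.counts
    for j, taxon in enumerate(matrix.taxa):
        tip_node = tree.tip_index[taxon]
        born_here = keep & (origin == tip_node)
        older = keep & (origin != tip_node) & presence[:, j]
        og_gains = int(born_here.sum())
        gene_gains = int(counts[born_here, j].sum()) + int(
            np.maximum(counts[older, j] - 1, 0).sum()
        )
        rows.append(
            {"taxon": taxon, "orthogroup_gains": og_gains, "gene_gains": gene_gains}
        )
    tip_gains = pd.DataFrame(rows, columns=["taxon", "orthogroup_gains", "gene_gains"])
    return GainLossSummary(tree, per_node, tip_gains, n_dropped)


@dataclass
class TopologyContrast:
    """Gain/loss summaries under two root hypotheses plus shared-clade deltas."""

    summary_a: GainLossSummary
    summary_b: GainLossSummary
    deltas: pd.DataFrame  # clade, n_origins_a, n_origins_b, n_losses_a, n_losses_b


def topology_contrast(
    matrix: OrthogroupMatrix, tree_a: RootedTree, tree_b: RootedTree
) -> TopologyContrast:
    """Contrast reconstructions under two topologies with the same tip set."""
    if tree_a.tips != tree_b.tips:
        raise TreeError(
            f"tip sets differ: {sorted(tree_a.tips ^ tree_b.tips)}"
        )
    sa = summarize_gain_loss(matrix, tree_a)
    sb = summarize_gain_loss(matrix, tree_b)
    ca, cb = sa.by_clade(), sb.by_clade()
    rows = []
    for clade in sorted(set(ca) & set(cb), key=lambda s: (len(s), sorted(s))):
        oa, la = ca[clade]
        ob, lb = cb[clade]
        rows.append(
            {
                "clade": ",".join(sorted(clade)),
                "n_origins_a": oa,
                "n_origins_b": ob,
                "delta_origins": ob - oa,
                "n_losses_a": la,
                "n_losses_b": lb,
                "delta_losses": lb - la,
            }
        )
    deltas = pd.DataFrame(
        rows,
        columns=[
            "clade", "n_origins_a", "n_origins_b", "delta_origins",
            "n_losses_a", "n_losses_b", "delta_losses",
        ],
    )
    return TopologyContrast(sa, sb, deltas)
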