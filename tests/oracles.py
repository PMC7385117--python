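"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive — exhaustive enumeration, double
loops, Fractions — and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


def hypergeom_upper_tail_exact(k: int, n_total: int, row: int, col: int) -> float:
    """P[X >= k] for X ~ Hypergeom(n_total, row, col), by exact rational enumeration."""
    denom = comb(n_total, col)
    total = Fraction(0)
    for i in range(k, min(row, col) + 1):
        total += Fraction(comb(row, i) * comb(n_total - row, col - i), denom)
    return float(total)


def lis_exhaustive(seq: list[int]) -> int:
    """Longest strictly increasing subsequence by scanning every subsequence."""
    best = 0
    n = len(seq)
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            sub = [seq[i] for i in combo]
            if all(a < b for a, b in zip(sub, sub[1:])):
                best = max(best, r)
    return best


def dollo_min_assignment(tree, present_tips: set[str]) -> tuple[int, frozenset[int]]:
    """Minimal single-gain (Dollo) explanation by exhaustive state enumeration.

    Enumerates every presence/absence assignment to the internal nodes that
    is consistent with the tips, keeps those with exactly one 0->1 edge
    (counting a present root as the gain), and returns the assignment with
    the fewest 1->0 edges as (gain node, loss-edge child nodes).
    """
    internal = [i for i in range(tree.n_nodes) if not tree.is_tip(i)]
    tip_state = {
        i: (tree.labels[i] in present_tips)
        for i in range(tree.n_nodes)
        if tree.is_tip(i)
    }
    best: tuple[int, frozenset[int]] | None = None
    for bits in itertools.product((False, True), repeat=len(internal)):
        state = dict(tip_state)
        state.update(zip(internal, bits))
        gains = [
            i
            for i in range(tree.n_nodes)
            if state[i] and (tree.parent[i] == -1 or not state[tree.parent[i]])
        ]
        if len(gains) != 1:
            continue
        losses = frozenset(
            i
            for i in range(tree.n_nodes)
            if tree.parent[i] != -1 and not state[i] and state[tree.parent[i]]
        )
        if best is None or len(losses) < len(best[1]):
            best = (gains[0], losses)
    assert best is not None, "no single-gain assignment exists"
    return best


def rbh_double_loop(hits_ab, hits_ba) -> set[tuple[str, str]]:
    """Reciprocal best hits by exhaustive double loops over the raw rows.

    Mirrors the documented policy: best HSP per (query, subject); best
    subject per query by (bitscore desc, e-value asc); queries whose top two
    distinct subjects tie on both keys are ambiguous and excluded.
    """

    def best_map(hits):
        collapsed = {}
        for h in hits:
            if h.query_id == h.subject_id:
                continue
            key = (h.query_id, h.subject_id)
            if key not in collapsed:
                collapsed[key] = h
            else:
                old = collapsed[key]
                if (h.bitscore, -h.evalue) > (old.bitscore, -old.evalue):
                    collapsed[key] = h
        out = {}
        for (q, s), h in collapsed.items():
            out.setdefault(q, []).append(h)
        best = {}
        for q, rows in out.items():
            top = None
            tied = False
            for h in rows:
                if top is None:
                    top, tied = h, False
                elif (h.bitscore, -h.evalue) > (top.bitscore, -top.evalue):
                    top, tied = h, False
                elif (h.bitscore, h.evalue) == (top.bitscore, top.evalue):
                    tied = True
            best[q] = None if tied else top.subject_id
        return best

    best_ab = best_map(hits_ab)
    best_ba = best_map(hits_ba)
    pairs = set()
    for a, b in best_ab.items():
        if b is None:
            continue
        if best_ba.get(b) == a:
            pairs.add((a, b))
    return pairs


def connected_components_bfs(edges, nodes) -> set[frozenset[str]]:
    """Connected components by explicit breadth-first search."""
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    seen: set[str] = set()
    comps: set[frozenset[str]] = set()
    for start in adj:
        if start in seen:
            continue
        comp = {start}
        queue = [start]
        while queue:
            u = queue.pop()
            for v in adj[u]:
                if v not in comp:
                    comp.add(v)
                    queue.append(v)
        seen |= comp
        comps.add(frozenset(comp))
    return comps


def t_test_formulas(a, b, pooled: bool):
    """Two-sample t statistic and df from the textbook formulas."""
    import math

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    if pooled:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    return (ma - mb) / se, df


def random_rooted_topologies(n_tips: int):
    """Every labelled rooted binary topology on tips t1..tn, as Newick strings."""
    labels = [f"t{i}" for i in range(1, n_tips + 1)]

    def build(tips: tuple[str, ...]):
        if len(tips) == 1:
            yield tips[0]
            return
        first, rest = tips[0], tips[1:]
        # choose the subset joining `first` on the left of the root split
        for r in range(len(rest)):
            for combo in itertools.combinations(rest, r):
                left = (first,) + combo
                right = tuple(t for t in rest if t not in combo)
                if not right:
                    continue
                for lt in build(left):
                    for rt in build(right):
                        yield f"({lt},{rt})"

    for nwk in build(tuple(labels)):
        yield nwk + ";"
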