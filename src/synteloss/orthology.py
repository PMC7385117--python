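"""One-to-one orthology by reciprocal best hits, and within-genome gene families.

The RBH pairing is the classic proxy for one-to-one orthology: a pair
(a, b) is kept iff b is a's unique best subject and a is b's unique best
subject.  "Best" is decided by bitscore, then e-value; a gene whose top two
distinct subjects are still tied after both keys is ambiguous and excluded
from the pairing (ambiguous genes would pollute downstream synteny counts).
Multiple HSP rows for the same (query, subject) collapse to the
max-bitscore row first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import DataWarning, SimilarityHit

__all__ = [
    "OrthologPairing",
    "GeneFamilyAssignment",
    "reciprocal_best_hits",
    "cluster_self_hits",
    "binarize",
]


@dataclass
class OrthologPairing:
    """One-to-one gene pairs between two species (symmetric by construction)."""

    species_a: str
    species_b: str
    pairs: set[tuple[str, str]]

    def __post_init__(self):
        a_seen: set[str] = set()
        b_seen: set[str] = set()
        for a, b in self.pairs:
            if a in a_seen or b in b_seen:
                raise ValueError(f"pairing is not one-to-one at ({a}, {b})")
            a_seen.add(a)
            b_seen.add(b)


@dataclass
class GeneFamilyAssignment:
    """Partition of one species' genes into similarity families."""

    species_id: str
    family_of: dict[str, str]

    def families(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene, fam in self.family_of.items():
            out.setdefault(fam, []).append(gene)
        for members in out.values():
            members.sort()
        return out


def _collapse_hsps(hits: list[SimilarityHit]) -> dict[tuple[str, str], SimilarityHit]:
    """Keep the best HSP per (query, subject): max bitscore, then min e-value."""
    best: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        prev = best.get(key)
        if prev is None or (h.bitscore, -h.evalue) > (prev.bitscore, -prev.evalue):
            best[key] = h
    return best


def _best_subjects(hits: list[SimilarityHit]) -> dict[str, str | None]:
    """Unique best subject per query under (bitscore desc, evalue asc).

    Returns ``None`` for queries whose top two distinct subjects tie on
    both keys (ambiguous).
    """
    collapsed = _collapse_hsps(hits)
    per_query: dict[str, list[SimilarityHit]] = {}
    for h in collapsed.values():
        if h.query_id == h.subject_id:
            continue
        per_query.setdefault(h.query_id, []).append(h)
    out: dict[str, str | None] = {}
    for q, rows in per_query.items():
        rows.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
        if len(rows) > 1 and (rows[0].bitscore, rows[0].evalue) == (
            rows[1].bitscore,
            rows[1].evalue,
        ):
            out[q] = None
        else:
            out[q] = rows[0].subject_id
    return out


def reciprocal_best_hits(
    hits_ab: list[SimilarityHit],
    hits_ba: list[SimilarityHit],
    species_a: str = "A",
    species_b: str = "B",
) -> OrthologPairing:
    """Reciprocal-best-hit pairing from A->B and B->A similarity tables.

    Raises if any gene id appears in both species' namespaces, since the
    orientation of such a hit is ambiguous.
    """
    genes_a = {h.query_id for h in hits_ab} | {h.subject_id for h in hits_ba}
    genes_b = {h.subject_id for h in hits_ab} | {h.query_id for h in hits_ba}
    shared = genes_a & genes_b
    if shared:
        raise ValueError(
            f"gene ids present in both species' namespaces: {sorted(shared)[:5]}"
        )
    best_ab = _best_subjects(hits_ab)
    best_ba = _best_subjects(hits_ba)
    pairs = {
        (a, b)
        for a, b in best_ab.items()
        if b is not None and best_ba.get(b) == a
    }
    return OrthologPairing(species_a, species_b, pairs)


def cluster_self_hits(
    self_hits: list[SimilarityHit],
    min_bitscore: float = 50.0,
    species_id: str = "A",
    genes: list[str] | None = None,
) -> GeneFamilyAssignment:
    """Single-linkage gene families from within-species similarity hits.

    Edges are hits with bitscore >= ``min_bitscore`` (self rows ignored);
    families are the connected components.  Genes listed in ``genes`` but
    hitting nothing become singleton families.  Family ids are
    ``fam<k>`` numbered by the lexicographically smallest member.
    """
    graph: nx.Graph = nx.Graph()
    if genes:
        graph.add_nodes_from(genes)
    for h in self_hits:
        if h.query_id == h.subject_id:
            continue
        graph.add_node(h.query_id)
        graph.add_node(h.subject_id)
        if h.bitscore >= min_bitscore:
            graph.add_edge(h.query_id, h.subject_id)
    comps = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    family_of = {
        gene: f"fam{k}" for k, comp in enumerate(comps) for gene in comp
    }
    return GeneFamilyAssignment(species_id, family_of)


def binarize(matrix) -> np.ndarray:
    """Binary presence view of an orthogroup matrix (count >= 1).

    All-absent rows are legal here; they are dropped (with a warning) by the
    gain/loss reconstruction, which cannot place an origin for them.
    """
    presence = matrix.presence()
    n_empty = int((~presence.any(axis=1)).sum())
    if n_empty:
        warnings.warn(
            f"{n_empty} orthogroup(s) absent from every taxon", DataWarning
        )
    return presence
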