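"""Oxford grids, macrosynteny enrichment, co-linearity, tandem/segmental duplications.

An Oxford grid tabulates one-to-one ortholog pairs by (scaffold_a,
scaffold_b).  A cell is *macrosyntenic* when its pair count is enriched
beyond chance given the scaffolds' marginal pair counts — upper-tail
hypergeometric test over the pair universe, Benjamini-Hochberg corrected
across the non-empty cells of the species pair.  Within a significant cell,
co-linearity is quantified by Spearman's rho on within-scaffold ranks and
by the longest strictly monotone subsequence fraction (``lis_fraction``),
which scores a whole-arm inversion as 1.  Cells that are enriched but not
co-linear carry the double-cut-and-join / dosage-sensitivity signature:
gene content is conserved on the same chromosome while local order is
shuffled.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataWarning, GenomeAnnotation, SimilarityHit
from .orthology import GeneFamilyAssignment, OrthologPairing

__all__ = [
    "SyntenyCell",
    "TandemArray",
    "oxford_grid",
    "cell_enrichment",
    "colinearity_stats",
    "classify_cells",
    "analyze_synteny",
    "cells_to_frame",
    "detect_tandem_arrays",
    "self_dotplot",
    "longest_monotone_fraction",
]

LABELS = ("macrosyntenic_colinear", "macrosyntenic_shuffled", "not_syntenic")


@dataclass
class SyntenyCell:
    """One scaffold-pair cell of an Oxford grid."""

    scaffold_a: str
    scaffold_b: str
    n_shared: int
    row_margin: int
    col_margin: int
    n_total: int
    rank_pairs: list[tuple[int, int]] = field(default_factory=list, repr=False)
    p_hyper: float | None = None
    q_value: float | None = None
    spearman_rho: float | None = None
    lis_fraction: float | None = None
    label: str | None = None


@dataclass
class TandemArray:
    """A run of near-adjacent same-family gene copies on one scaffold."""

    species_id: str
    scaffold_id: str
    family_id: str
    member_ranks: list[int]
    member_genes: list[str]

    @property
    def size(self) -> int:
        return len(self.member_ranks)


def oxford_grid(
    pairing: OrthologPairing,
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    missing: str = "warn",
) -> list[SyntenyCell]:
    """Tabulate ortholog pairs per scaffold pair; cells with zero pairs are omitted.

    The enrichment universe is ortholog *pairs*: ``n_total`` counts pairs
    with both genes annotated, and margins count pairs per scaffold over
    that same universe.  Pairs with an unannotated gene are dropped with a
    warning (``missing="warn"``) or raise (``missing="error"``).
    """
    kept: list[tuple[str, str, int, int]] = []
    n_dropped = 0
    for a, b in pairing.pairs:
        if a not in annot_a or b not in annot_b:
            if missing == "error":
                raise KeyError(f"paired gene missing from annotation: ({a}, {b})")
            n_dropped += 1
            continue
        la, lb = annot_a.locus(a), annot_b.locus(b)
        kept.append((la.scaffold_id, lb.scaffold_id, la.rank, lb.rank))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} pair(s) missing from the annotations", DataWarning
        )
    n_total = len(kept)
    cells: dict[tuple[str, str], list[tuple[int, int]]] = {}
    row_margin: dict[str, int] = {}
    col_margin: dict[str, int] = {}
    for sa, sb, ra, rb in kept:
        cells.setdefault((sa, sb), []).append((ra, rb))
        row_margin[sa] = row_margin.get(sa, 0) + 1
        col_margin[sb] = col_margin.get(sb, 0) + 1
    return [
        SyntenyCell(
            scaffold_a=sa,
            scaffold_b=sb,
            n_shared=len(pairs),
            row_margin=row_margin[sa],
            col_margin=col_margin[sb],
            n_total=n_total,
            rank_pairs=sorted(pairs),
        )
        for (sa, sb), pairs in sorted(cells.items())
    ]


def cell_enrichment(cells: list[SyntenyCell]) -> list[SyntenyCell]:
    """Upper-tail hypergeometric p per cell plus Benjamini-Hochberg q-values.

    p = P[X >= n_shared] with X ~ Hypergeom(population n_total, successes
    row_margin, draws col_margin); BH is applied across all supplied
    (non-empty) cells, i.e. scoped to one species pair's grid.
    """
    if not cells:
        return cells
    for c in cells:
        if c.n_shared > min(c.row_margin, c.col_margin) or max(
            c.row_margin, c.col_margin
        ) > c.n_total:
            raise ValueError(
                f"inconsistent margins in cell ({c.scaffold_a}, {c.scaffold_b})"
            )
    k = np.array([c.n_shared for c in cells])
    n_tot = np.array([c.n_total for c in cells])
    row = np.array([c.row_margin for c in cells])
    col = np.array([c.col_margin for c in cells])
    p = stats.hypergeom.sf(k - 1, n_tot, row, col)
    p = np.clip(p, 0.0, 1.0)
    q = stats.false_discovery_control(p, method="bh")
    for c, pi, qi in zip(cells, p, q):
        c.p_hyper = float(pi)
        c.q_value = float(qi)
    return cells


def _lis_length(seq: list[int]) -> int:
    """Length of the longest strictly increasing subsequence (patience sorting)."""
    tails: list[int] = []
    for x in seq:
        i = bisect_left(tails, x)
        if i == len(tails):
            tails.append(x)
        else:
            tails[i] = x
    return len(tails)


def longest_monotone_fraction(rank_pairs: list[tuple[int, int]]) -> float:
    """max(LIS, LDS) of rank_b ordered by rank_a, divided by the pair count.

    Equals 1 for perfectly co-linear cells in either orientation, so a
    whole-arm inversion still scores 1.
    """
    seq = [rb for _, rb in sorted(rank_pairs)]
    n = len(seq)
    return max(_lis_length(seq), _lis_length([-x for x in seq])) / n


def colinearity_stats(
    rank_pairs: list[tuple[int, int]],
) -> tuple[float | None, float]:
    """(spearman_rho, lis_fraction) for one cell's within-scaffold rank pairs.

    rho is undefined (None) for fewer than 3 pairs; fewer than 2 pairs is
    the caller's degenerate case and raises.
    """
    if len(rank_pairs) < 2:
        raise ValueError("co-linearity needs at least 2 pairs")
    lis_frac = longest_monotone_fraction(rank_pairs)
    if len(rank_pairs) < 3:
        return None, lis_frac
    ra = [a for a, _ in rank_pairs]
    rb = [b for _, b in rank_pairs]
    rho = float(stats.spearmanr(ra, rb).statistic)
    return rho, lis_frac


def classify_cells(
    cells: list[SyntenyCell],
    q_max: float = 0.05,
    min_pairs: int = 5,
    colinear_min: float = 0.8,
) -> list[SyntenyCell]:
    """Label each cell: not_syntenic / macrosyntenic_colinear / macrosyntenic_shuffled.

    A cell must pass both the FDR threshold and the minimum pair count to be
    called macrosyntenic; co-linear cells are those whose longest monotone
    subsequence covers at least ``colinear_min`` of the pairs.
    """
    for c in cells:
        if c.q_value is None:
            raise ValueError("run cell_enrichment before classify_cells")
        if c.n_shared >= 2:
            c.spearman_rho, c.lis_fraction = colinearity_stats(c.rank_pairs)
        if c.q_value > q_max or c.n_shared < min_pairs:
            c.label = "not_syntenic"
        elif c.lis_fraction is not None and c.lis_fraction >= colinear_min:
            c.label = "macrosyntenic_colinear"
        else:
            c.label = "macrosyntenic_shuffled"
    return cells


def analyze_synteny(
    pairing: OrthologPairing,
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    q_max: float = 0.05,
    min_pairs: int = 5,
    colinear_min: float = 0.8,
    missing: str = "warn",
) -> list[SyntenyCell]:
    """Full grid -> enrichment -> classification pipeline for one species pair."""
    cells = oxford_grid(pairing, annot_a, annot_b, missing=missing)
    cell_enrichment(cells)
    return classify_cells(cells, q_max=q_max, min_pairs=min_pairs,
                          colinear_min=colinear_min)


def cells_to_frame(cells: list[SyntenyCell]) -> pd.DataFrame:
    """Tabular view with a fixed, documented column order."""
    return pd.DataFrame(
        [
            {
                "scaffold_a": c.scaffold_a,
                "scaffold_b": c.scaffold_b,
                "n_shared": c.n_shared,
                "row_margin": c.row_margin,
                "col_margin": c.col_margin,
                "n_total": c.n_total,
                "p_hyper": c.p_hyper,
                "q_value": c.q_value,
                "spearman_rho": c.spearman_rho,
                "lis_fraction": c.lis_fraction,
                "label": c.label,
            }
            for c in cells
        ],
        columns=[
            "scaffold_a", "scaffold_b", "n_shared", "row_margin", "col_margin",
            "n_total", "p_hyper", "q_value", "spearman_rho", "lis_fraction", "label",
        ],
    )


def detect_tandem_arrays(
    annot: GenomeAnnotation,
    families: GeneFamilyAssignment,
    max_gap: int = 0,
) -> list[TandemArray]:
    """Maximal same-family runs on one scaffold with <= max_gap intervening genes.

    Consecutive member ranks may differ by at most ``max_gap + 1``; runs of
    size >= 2 are reported.
    """
    arrays: list[TandemArray] = []
    for scaf, loci in annot.scaffolds.items():
        per_family: dict[str, list[GeneLocusLike]] = {}
        for locus in loci:
            fam = families.family_of.get(locus.gene_id)
            if fam is not None:
                per_family.setdefault(fam, []).append(locus)
        for fam in sorted(per_family):
            members = sorted(per_family[fam], key=lambda l: l.rank)
            run = [members[0]]
            for locus in members[1:]:
                if locus.rank - run[-1].rank <= max_gap + 1:
                    run.append(locus)
                else:
                    if len(run) >= 2:
                        arrays.append(_make_array(annot.species_id, scaf, fam, run))
                    run = [locus]
            if len(run) >= 2:
                arrays.append(_make_array(annot.species_id, scaf, fam, run))
    return arrays


GeneLocusLike = object  # loci from io.GenomeAnnotation


def _make_array(species_id, scaf, fam, run) -> TandemArray:
    return TandemArray(
        species_id=species_id,
        scaffold_id=scaf,
        family_id=fam,
        member_ranks=[l.rank for l in run],
        member_genes=[l.gene_id for l in run],
    )


def self_dotplot(
    annot: GenomeAnnotation,
    self_hits: list[SimilarityHit],
    scaffold: str,
) -> list[tuple[int, int, str]]:
    """Segmental-duplicate dotplot points for one scaffold.

    One point per within-scaffold hit (query != subject) plus its symmetric
    mirror; orientation is ``forward`` when strands match, ``reverse``
    otherwise (hits involving a gene of unknown strand are ``unknown``).
    """
    if scaffold not in annot.scaffolds:
        raise KeyError(f"unknown scaffold {scaffold!r} in {annot.species_id}")
    on_scaf = {l.gene_id: l for l in annot.scaffolds[scaffold]}
    points: list[tuple[int, int, str]] = []
    for h in self_hits:
        if h.query_id == h.subject_id:
            continue
        lq = on_scaf.get(h.query_id)
        ls = on_scaf.get(h.subject_id)
        if lq is None or ls is None:
            continue
        if "?" in (lq.strand, ls.strand):
            orient = "unknown"
        else:
            orient = "forward" if lq.strand == ls.strand else "reverse"
        points.append((lq.rank, ls.rank, orient))
        points.append((ls.rank, lq.rank, orient))
    return points
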