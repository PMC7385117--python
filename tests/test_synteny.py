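"""Oxford grids, enrichment, co-linearity, tandem arrays, self dotplots."""

import random
from fractions import Fraction
from math import comb

import pytest

from synteloss import (
    GenomeAnnotation,
    OrthologPairing,
    SimilarityHit,
    cell_enrichment,
    classify_cells,
    colinearity_stats,
    detect_tandem_arrays,
    oxford_grid,
    self_dotplot,
)
from synteloss.io import DataWarning
from synteloss.orthology import GeneFamilyAssignment
from synteloss.synteny import SyntenyCell, analyze_synteny, longest_monotone_fraction

from oracles import hypergeom_upper_tail_exact, lis_exhaustive


def annot_from_ranks(species: str, layout: dict[str, list[str]]) -> GenomeAnnotation:
    """layout: scaffold -> gene ids in rank order."""
    records = []
    for scaf, genes in layout.items():
        for i, g in enumerate(genes):
            records.append((scaf, i * 100, i * 100 + 50, g, "+"))
    return GenomeAnnotation.from_records(species, records)


# --------------------------------------------------------------- oxford grid


def test_single_cell_counts_and_margins():
    a = annot_from_ranks("A", {"sA1": ["a1", "a2", "a3", "a4"]})
    b = annot_from_ranks("B", {"sB1": ["b1", "b2", "b3", "b4"]})
    pairing = OrthologPairing("A", "B", {(f"a{i}", f"b{i}") for i in range(1, 5)})
    cells = oxford_grid(pairing, a, b)
    assert len(cells) == 1
    c = cells[0]
    assert (c.n_shared, c.row_margin, c.col_margin, c.n_total) == (4, 4, 4, 4)


def test_disjoint_cells_margins():
    a = annot_from_ranks("A", {"sA1": ["a1", "a2"], "sA2": ["a3"]})
    b = annot_from_ranks("B", {"sB1": ["b1", "b2"], "sB2": ["b3"]})
    pairing = OrthologPairing("A", "B", {("a1", "b1"), ("a2", "b2"), ("a3", "b3")})
    cells = {(c.scaffold_a, c.scaffold_b): c for c in oxford_grid(pairing, a, b)}
    assert cells[("sA1", "sB1")].n_shared == 2
    assert cells[("sA2", "sB2")].n_shared == 1
    assert cells[("sA1", "sB1")].row_margin == 2
    assert cells[("sA2", "sB2")].col_margin == 1
    assert all(c.n_total == 3 for c in cells.values())


def test_grid_counts_match_nested_loop_tally():
    rng = random.Random(3)
    scafs_a = {f"sA{i}": [f"a{i}_{j}" for j in range(20)] for i in range(3)}
    scafs_b = {f"sB{i}": [f"b{i}_{j}" for j in range(20)] for i in range(3)}
    a = annot_from_ranks("A", scafs_a)
    b = annot_from_ranks("B", scafs_b)
    all_a = [g for genes in scafs_a.values() for g in genes]
    all_b = [g for genes in scafs_b.values() for g in genes]
    pairs = set(zip(rng.sample(all_a, 50), rng.sample(all_b, 50)))
    cells = oxford_grid(OrthologPairing("A", "B", pairs), a, b)
    # oracle: independent nested-loop count
    def scaffold_of(g, layout):
        return next(s for s, genes in layout.items() if g in genes)
    tally: dict[tuple[str, str], int] = {}
    for ga, gb in pairs:
        key = (scaffold_of(ga, scafs_a), scaffold_of(gb, scafs_b))
        tally[key] = tally.get(key, 0) + 1
    assert {(c.scaffold_a, c.scaffold_b): c.n_shared for c in cells} == tally
    assert sum(c.n_shared for c in cells) == len(pairs) == cells[0].n_total


def test_missing_gene_policy(tmp_path):
    a = annot_from_ranks("A", {"sA1": ["a1"]})
    b = annot_from_ranks("B", {"sB1": ["b1"]})
    pairing = OrthologPairing("A", "B", {("a1", "b1"), ("a2", "b2")})
    with pytest.warns(DataWarning, match="dropped 1"):
        cells = oxford_grid(pairing, a, b)
    assert cells[0].n_total == 1
    with pytest.raises(KeyError):
        oxford_grid(pairing, a, b, missing="error")


# ---------------------------------------------------------------- enrichment


def _cell(k, row, col, n):
    return SyntenyCell("x", "y", k, row, col, n)


def test_enrichment_examples():
    cells = cell_enrichment([_cell(0, 5, 8, 20)])
    assert cells[0].p_hyper == pytest.approx(1.0)
    cells = cell_enrichment([_cell(4, 5, 8, 20)])
    assert cells[0].p_hyper == pytest.approx(
        float(Fraction(comb(5, 4) * comb(15, 4) + comb(5, 5) * comb(15, 3),
                       comb(20, 8))),
        abs=1e-12,
    )
    cells = cell_enrichment([_cell(7, 7, 7, 7)])  # all pairs in one cell
    assert cells[0].p_hyper == pytest.approx(1.0)


def test_enrichment_matches_exact_oracle_small_margins():
    rng = random.Random(1)
    for _ in range(200):
        n = rng.randint(1, 20)
        row = rng.randint(0, n)
        col = rng.randint(0, n)
        k = rng.randint(0, min(row, col))
        cells = cell_enrichment([_cell(k, row, col, n)])
        assert cells[0].p_hyper == pytest.approx(
            hypergeom_upper_tail_exact(k, n, row, col), abs=1e-12
        )


def test_bh_q_at_least_p_and_scoped_to_supplied_cells():
    cells = cell_enrichment(
        [_cell(5, 6, 6, 30), _cell(1, 6, 6, 30), _cell(2, 10, 10, 30)]
    )
    for c in cells:
        assert c.q_value >= c.p_hyper - 1e-15


def test_inconsistent_margins_error():
    with pytest.raises(ValueError, match="inconsistent"):
        cell_enrichment([_cell(5, 3, 8, 20)])


# --------------------------------------------------------------- colinearity


def test_colinearity_identity_reversal_and_mixed():
    rho, lis = colinearity_stats([(i, i) for i in range(5)])
    assert rho == pytest.approx(1.0) and lis == 1.0
    rho, lis = colinearity_stats([(i, 4 - i) for i in range(5)])
    assert rho == pytest.approx(-1.0) and lis == 1.0
    rho, lis = colinearity_stats(list(enumerate([1, 3, 2, 4])))
    assert rho == pytest.approx(0.8)
    assert lis == pytest.approx(0.75)


def test_colinearity_undefined_cases():
    with pytest.raises(ValueError):
        colinearity_stats([(0, 0)])
    rho, lis = colinearity_stats([(0, 1), (1, 0)])
    assert rho is None and lis == 1.0  # strictly decreasing pair


@pytest.mark.parametrize("seed", range(8))
def test_lis_fraction_matches_exhaustive_and_reversal_invariant(seed):
    rng = random.Random(seed)
    n = rng.randint(2, 9)
    ranks_b = rng.sample(range(n), n)
    pairs = list(enumerate(ranks_b))
    frac = longest_monotone_fraction(pairs)
    oracle = max(lis_exhaustive(ranks_b), lis_exhaustive([-x for x in ranks_b])) / n
    assert frac == pytest.approx(oracle)
    # invariance under global reversal of either axis
    rev_a = [((n - 1) - a, b) for a, b in pairs]
    rev_b = [(a, (n - 1) - b) for a, b in pairs]
    assert longest_monotone_fraction(rev_a) == pytest.approx(frac)
    assert longest_monotone_fraction(rev_b) == pytest.approx(frac)


# ------------------------------------------------------------ classification


def test_classification_thresholds():
    colinear = _cell(6, 6, 6, 60)
    colinear.rank_pairs = [(i, i) for i in range(6)]
    shuffled = _cell(8, 8, 8, 60)
    shuffled.rank_pairs = list(enumerate([3, 7, 1, 5, 0, 6, 2, 4]))
    weak = _cell(2, 4, 4, 60)
    weak.rank_pairs = [(0, 0), (1, 1)]
    cells = classify_cells(cell_enrichment([colinear, shuffled, weak]))
    assert colinear.label == "macrosyntenic_colinear"
    assert shuffled.label == "macrosyntenic_shuffled"
    assert weak.label == "not_syntenic"  # below min_pairs
    high_q = _cell(3, 20, 20, 40)
    high_q.rank_pairs = [(0, 0), (1, 1), (2, 2)]
    classify_cells(cell_enrichment([high_q]), q_max=0.05)
    assert high_q.q_value > 0.05 and high_q.label == "not_syntenic"


# -------------------------------------------------------------------- tandem


def fam(species, mapping):
    return GeneFamilyAssignment(species, mapping)


def test_tandem_examples():
    layout = {"s1": [f"g{i}" for i in range(10)]}
    annot = annot_from_ranks("A", layout)
    # single-copy family: nothing
    families = fam("A", {g: g for g in layout["s1"]})
    assert detect_tandem_arrays(annot, families) == []
    # ranks 3,4,5 max_gap 0 -> one array of size 3
    mapping = {g: "other" for g in layout["s1"]}
    for g in ("g3", "g4", "g5"):
        mapping[g] = "famX"
    arrays = detect_tandem_arrays(annot, fam("A", mapping), max_gap=0)
    arrays = [a for a in arrays if a.family_id == "famX"]
    assert len(arrays) == 1 and arrays[0].member_ranks == [3, 4, 5]
    # ranks 2,4,7 max_gap 1 -> {2,4}, 7 excluded
    mapping = {g: g for g in layout["s1"]}
    for g in ("g2", "g4", "g7"):
        mapping[g] = "famY"
    arrays = detect_tandem_arrays(annot, fam("A", mapping), max_gap=1)
    assert len(arrays) == 1 and arrays[0].member_ranks == [2, 4]


@pytest.mark.parametrize("seed", range(8))
def test_tandem_matches_window_scan_oracle(seed):
    rng = random.Random(seed)
    n, max_gap = 30, rng.randint(0, 2)
    genes = [f"g{i}" for i in range(n)]
    annot = annot_from_ranks("A", {"s1": genes})
    mapping = {g: f"fam{rng.randint(0, 4)}" for g in genes}
    got = {
        (a.family_id, tuple(a.member_ranks))
        for a in detect_tandem_arrays(annot, fam("A", mapping), max_gap=max_gap)
    }
    # oracle: exhaustive scan per family
    expected = set()
    for f in set(mapping.values()):
        ranks = [i for i, g in enumerate(genes) if mapping[g] == f]
        run = [ranks[0]] if ranks else []
        for r in ranks[1:]:
            if r - run[-1] <= max_gap + 1:
                run.append(r)
            else:
                if len(run) >= 2:
                    expected.add((f, tuple(run)))
                run = [r]
        if len(run) >= 2:
            expected.add((f, tuple(run)))
    assert got == expected


# ------------------------------------------------------------------- dotplot


def test_self_dotplot_points_and_errors():
    records = [
        ("s22", i * 100, i * 100 + 50, f"g{i}", "+" if i != 9 else "-")
        for i in range(10)
    ]
    annot = GenomeAnnotation.from_records("A", records)
    assert self_dotplot(annot, [], "s22") == []
    pts = self_dotplot(annot, [SimilarityHit("g2", "g5", 1e-20, 99)], "s22")
    assert sorted(pts) == [(2, 5, "forward"), (5, 2, "forward")]
    pts = self_dotplot(annot, [SimilarityHit("g2", "g9", 1e-20, 99)], "s22")
    assert sorted(pts) == [(2, 9, "reverse"), (9, 2, "reverse")]
    with pytest.raises(KeyError, match="nope"):
        self_dotplot(annot, [], "nope")
    # self rows and off-scaffold genes ignored
    pts = self_dotplot(
        annot,
        [SimilarityHit("g2", "g2", 0, 99), SimilarityHit("g2", "zz", 0, 99)],
        "s22",
    )
    assert pts == []
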