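"""Simulator: determinism, model invariants, event-log replay, planted truths."""

import filecmp
from pathlib import Path

import numpy as np
import pytest

from synteloss import SimConfig, simulate_dataset
from synteloss.convergence import HabitatPanel, shared_loss_counts, lineage_loss_set
from synteloss.orthology import reciprocal_best_hits
from synteloss.simulate import (
    balanced_pair_tree,
    emit_dataset,
    replay_events,
    simulate_gene_content_fast,
    similarity_tables,
)
from synteloss.trees import RootedTree

QUARTET = "((A:1,B:1):0.5,(C:1,D:1):0.5);"


def small_config(**overrides) -> SimConfig:
    base = dict(
        tree=QUARTET, seed=7, root_orthogroups=120, gain_rate=2.0, loss_rate=0.15,
        duplication_rate=0.05, n_chromosomes=3, inversion_rate=3.0,
        translocation_rate=0.2, p_tandem=0.7,
    )
    base.update(overrides)
    return SimConfig(**base)


def test_identical_config_and_seed_byte_identical_output(tmp_path):
    cfg = small_config()
    for sub in ("run1", "run2"):
        emit_dataset(simulate_dataset(cfg), tmp_path / sub)
    files1 = sorted(p.name for p in (tmp_path / "run1").iterdir())
    files2 = sorted(p.name for p in (tmp_path / "run2").iterdir())
    assert files1 == files2
    match, mismatch, errors = filecmp.cmpfiles(
        tmp_path / "run1", tmp_path / "run2", files1, shallow=False
    )
    assert mismatch == [] and errors == []


def test_zero_rates_tips_equal_root():
    cfg = small_config(gain_rate=0, loss_rate=0, duplication_rate=0,
                       inversion_rate=0, translocation_rate=0)
    r = simulate_dataset(cfg)
    root_state = r.content[r.tree.root]
    for node in r.tree.tip_index.values():
        assert r.content[node] == root_state
        assert r.genomes[node] == r.genomes[r.tree.root]
    assert (r.matrix.counts == 1).all()


def test_no_translocations_preserve_chromosome_assignment():
    cfg = small_config(translocation_rate=0.0, inversion_rate=5.0, seed=3)
    r = simulate_dataset(cfg)
    root_chrom = {
        uid: c
        for c, chrom in enumerate(r.genomes[r.tree.root])
        for uid, _, _ in chrom
    }
    for node in r.tree.tip_index.values():
        for c, chrom in enumerate(r.genomes[node]):
            for uid, _, _ in chrom:
                if uid in root_chrom:
                    assert root_chrom[uid] == c


def test_event_log_replay_reproduces_every_tip():
    r = simulate_dataset(small_config(seed=11))
    replayed = replay_events(r.tree, r.genomes[r.tree.root], r.events)
    for node in r.tree.tip_index.values():
        assert replayed[node] == r.genomes[node]
    # inversions flip strands somewhere
    strands = {
        s for node in r.tree.tip_index.values()
        for chrom in r.genomes[node] for _, _, s in chrom
    }
    assert strands == {"+", "-"}


def test_gain_rate_poisson_mean():
    tree = RootedTree.from_newick("(A:1,B:1);")
    gamma, n_seeds = 5.0, 200
    totals = []
    for seed in range(n_seeds):
        cfg = SimConfig(tree="(A:1,B:1);", seed=seed, root_orthogroups=10,
                        gain_rate=gamma, loss_rate=0.0, simulate_order=False)
        r = simulate_dataset(cfg)
        for ev in r.events:
            if ev.node != r.tree.root:
                totals.append(len(ev.gains))
    mean = np.mean(totals)
    se = np.sqrt(gamma / len(totals))  # Poisson variance = mean
    assert abs(mean - gamma) < 3 * se


def test_similarity_dropout_and_spurious():
    cfg = small_config(similarity_dropout=1.0, duplication_rate=0.0,
                       gain_rate=0.0, loss_rate=0.0)
    tabs = similarity_tables(simulate_dataset(cfg))
    assert all(not hits for (a, b), hits in tabs.items() if a != b)

    cfg = small_config(similarity_dropout=0.1, duplication_rate=0.0,
                       gain_rate=0.0, loss_rate=0.0, root_orthogroups=500)
    r = simulate_dataset(cfg)
    tabs = similarity_tables(r)
    kept = sum(len(tabs[(a, b)]) for (a, b) in tabs if a != b)
    n_expected = 500 * 4 * 3  # every ortholog pair, both directions, 6 pairs
    frac = kept / n_expected
    se = np.sqrt(0.9 * 0.1 / n_expected)
    assert abs(frac - 0.9) < 4 * se


def test_rbh_recovers_planted_map_without_noise_or_paralogy():
    cfg = small_config(duplication_rate=0.0, seed=5)
    r = simulate_dataset(cfg)
    tabs = similarity_tables(r)
    for a, b in [("A", "B"), ("A", "C"), ("B", "D")]:
        pairing = reciprocal_best_hits(tabs[(a, b)], tabs[(b, a)], a, b)
        assert pairing.pairs == r.ortholog_map(a, b)


# ------------------------------------------------------------------- planting


PANEL4 = [("P1", "m1", "f1"), ("P2", "m2", "f2"),
          ("P3", "m3", "f3"), ("P4", "m4", "f4")]


def test_planted_convergent_losses_recovered_end_to_end():
    tree = balanced_pair_tree(4, tip_length=1.0, stem_length=0.1)
    cfg = SimConfig(tree=tree, seed=2, root_orthogroups=100, gain_rate=0.0,
                    loss_rate=0.0, planted_convergent_losses=10, panel=PANEL4,
                    simulate_order=False)
    r = simulate_dataset(cfg)
    assert len(r.planted_losses) == 10
    presence = r.matrix.presence()
    for og in r.planted_losses:
        row = presence[r.matrix.og_index[og]]
        for p, marine, fresh in PANEL4:
            assert row[r.matrix.taxon_index[marine]]
            assert not row[r.matrix.taxon_index[fresh]]
    panel = HabitatPanel(PANEL4)
    sets = [lineage_loss_set(r.matrix, p, "freshwater") for p in panel]
    count_all, _ = shared_loss_counts(sets)
    assert count_all == 10  # loss rate 0: planted losses only


def test_planting_zero_changes_nothing_and_infeasible_raises():
    tree = balanced_pair_tree(4)
    base = SimConfig(tree=tree, seed=2, root_orthogroups=50, gain_rate=0.0,
                     loss_rate=0.0, simulate_order=False)
    planted0 = SimConfig(tree=tree, seed=2, root_orthogroups=50, gain_rate=0.0,
                         loss_rate=0.0, planted_convergent_losses=0, panel=PANEL4,
                         simulate_order=False)
    a = simulate_dataset(base)
    b = simulate_dataset(planted0)
    assert (a.matrix.counts == b.matrix.counts).all()
    with pytest.raises(ValueError, match="plant"):
        simulate_dataset(SimConfig(
            tree=tree, seed=2, root_orthogroups=50, gain_rate=0.0, loss_rate=0.0,
            planted_convergent_losses=51, panel=PANEL4, simulate_order=False,
        ))


# ------------------------------------------------------------------ fast path


def test_fast_content_path_model_invariants():
    tree = RootedTree.from_newick(balanced_pair_tree(3))
    cfg = SimConfig(tree=balanced_pair_tree(3), seed=9, root_orthogroups=400,
                    gain_rate=1.0, loss_rate=0.5, duplication_rate=0.0)
    rng = np.random.default_rng(9)
    matrix, presence = simulate_gene_content_fast(cfg, tree, rng)
    # determinism
    m2, p2 = simulate_gene_content_fast(cfg, tree, np.random.default_rng(9))
    assert (matrix.counts == m2.counts).all() and (presence == p2).all()
    # Dollo: an orthogroup present at a node but absent at its parent must
    # have originated on that edge, so it is absent at every strict ancestor
    for node in range(1, tree.n_nodes):
        gained_here = presence[node] & ~presence[tree.parent[node]]
        u = tree.parent[node]
        while u != -1:
            assert not (gained_here & presence[u]).any()
            u = tree.parent[u]
    # tips match matrix columns
    taxa = sorted(tree.tips)
    for j, t in enumerate(taxa):
        assert (matrix.counts[:, j] == presence[tree.tip_index[t]]).all()


def test_fast_content_loss_probability_calibration():
    # one long branch: retention frequency matches exp(-loss_rate * length)
    tree_s = "(A:2.0,B:0.001);"
    tree = RootedTree.from_newick(tree_s)
    cfg = SimConfig(tree=tree_s, seed=1, root_orthogroups=4000, gain_rate=0.0,
                    loss_rate=0.4, duplication_rate=0.0)
    matrix, _ = simulate_gene_content_fast(cfg, tree, np.random.default_rng(1))
    frac = matrix.counts[:, 0].mean()  # taxon A, branch length 2
    expected = np.exp(-0.4 * 2.0)
    se = np.sqrt(expected * (1 - expected) / 4000)
    assert abs(frac - expected) < 4 * se
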