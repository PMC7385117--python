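"""Seeded simulator for gene content, gene order, and similarity tables.

The generative model mirrors the assumptions behind the downstream
analyses:

* **Gene content** evolves on a rooted tree under a strict Dollo regime:
  the root carries ``root_orthogroups`` single-copy orthogroups; along each
  branch new orthogroups arise as Poisson(gain_rate * length), each existing
  orthogroup is lost irreversibly with probability 1 - exp(-loss_rate *
  length), and each retained orthogroup gains Poisson(duplication_rate *
  length) extra copies.  Re-gain is disallowed, so Dollo reconstruction of
  the observable history is exact rather than approximate.

* **Gene order** evolves by within-chromosome inversions (which reverse a
  uniform random interval and flip member strands) and rare
  between-chromosome translocations of a random segment — the double cut
  and join / dosage-sensitivity regime in which chromosome membership is
  conserved while local order shuffles.  New duplicates insert adjacent to
  their parent copy with probability ``p_tandem`` (tandem arrays),
  otherwise uniformly.

* **Similarity tables** contain a mutual hit for every within-orthogroup
  gene pair (true ortholog copies score higher than paralogous copies, with
  a small seeded jitter breaking ties), then are degraded by per-row
  dropout and spurious random hits.

Every random draw comes from one ``numpy`` Generator seeded from the
config, so identical configs give byte-identical emitted files.  The event
log suffices to replay every tip genome from the root state, and the
simulator also records the *observable* projection of the planted history
(origin at the MRCA of surviving tips; losses as maximal absent subtrees),
which is what any reconstruction restricted to tip data can recover.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .convergence import HabitatPanel
from .io import (
    DataWarning,
    GenomeAnnotation,
    OrthogroupMatrix,
    SimilarityHit,
    write_annotation,
    write_orthogroups,
    write_similarity_table,
)
from .trees import RootedTree

__all__ = [
    "SimConfig",
    "BranchEvents",
    "SimResult",
    "simulate_gene_content",
    "plant_convergent_losses",
    "simulate_gene_order",
    "simulate_dataset",
    "emit_dataset",
    "replay_events",
    "observable_gain_loss",
]

# bitscore bases for emitted similarity rows
ORTHOLOG_BASE = 200.0
PARALOG_BASE = 100.0
SPURIOUS_BASE = 60.0


@dataclass
class SimConfig:
    """All knobs of one simulation run; identical config + seed => identical output."""

    tree: str  # Newick with branch lengths (unit lengths substituted if absent)
    seed: int = 0
    root_orthogroups: int = 600
    gain_rate: float = 5.0
    loss_rate: float = 0.3
    duplication_rate: float = 0.0
    n_chromosomes: int = 3
    inversion_rate: float = 5.0
    translocation_rate: float = 0.0
    p_tandem: float = 0.7
    similarity_dropout: float = 0.0
    spurious_hit_rate: float = 0.0
    planted_convergent_losses: int = 0
    panel: list[tuple[str, str, str]] | None = None
    simulate_order: bool = True

    def __post_init__(self):
        for name in (
            "gain_rate", "loss_rate", "duplication_rate",
            "inversion_rate", "translocation_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_tandem", "similarity_dropout", "spurious_hit_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class BranchEvents:
    """Events on the branch above one node (placements recorded for replay)."""

    node: int
    gains: list = field(default_factory=list)  # (og, uid, chrom, pos)
    losses: list = field(default_factory=list)  # (og, [uids])
    duplications: list = field(default_factory=list)  # (og, parent_uid, uid, chrom, pos, strand)
    inversions: list = field(default_factory=list)  # (chrom, i, j) reverse slice [i:j]
    translocations: list = field(default_factory=list)  # (src, i, j, dst, pos)


@dataclass
class SimResult:
    config: SimConfig
    tree: RootedTree
    content: list[dict[str, list[str]]]  # per node: og -> uids
    events: list[BranchEvents]
    matrix: OrthogroupMatrix
    genomes: list[list[list[tuple[str, str, str]]]] | None  # node -> chrom -> (uid, og, strand)
    annotations: dict[str, GenomeAnnotation]
    planted_losses: list[str]
    truth_origin: dict[str, int]  # og -> observable origin node
    truth_losses: dict[str, frozenset[int]]  # og -> observable loss-edge child nodes

    def truth_per_node(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_origins, n_losses) arrays over tree nodes from the observable truth."""
        origins = np.zeros(self.tree.n_nodes, dtype=np.int64)
        losses = np.zeros(self.tree.n_nodes, dtype=np.int64)
        for og, node in self.truth_origin.items():
            origins[node] += 1
        for og, children in self.truth_losses.items():
            for c in children:
                losses[c] += 1
        return origins, losses

    def ortholog_map(self, taxon_a: str, taxon_b: str) -> set[tuple[str, str]]:
        """Planted one-to-one ortholog pairs: gene copies sharing an ancestral uid."""
        ca = self.content[self.tree.tip_index[taxon_a]]
        cb = self.content[self.tree.tip_index[taxon_b]]
        uids_a = {u: og for og, us in ca.items() for u in us}
        uids_b = {u: og for og, us in cb.items() for u in us}
        return {
            (f"{taxon_a}_{u}", f"{taxon_b}_{u}")
            for u in set(uids_a) & set(uids_b)
        }


def _branch_lengths(tree: RootedTree) -> list[float]:
    if not tree.has_branch_lengths():
        warnings.warn("tree lacks branch lengths; using unit lengths", DataWarning)
        return [1.0] * tree.n_nodes
    return [tree.branch_length(i) for i in range(tree.n_nodes)]


def simulate_gene_content(
    config: SimConfig, tree: RootedTree, rng: np.random.Generator
) -> tuple[list[dict[str, list[str]]], list[BranchEvents]]:
    """Dollo gene-content evolution; returns per-node content and the event log."""
    lengths = _branch_lengths(tree)
    counter = {"og": 0, "uid": 0}

    def new_og() -> str:
        counter["og"] += 1
        return f"OG{counter['og']:05d}"

    def new_uid() -> str:
        counter["uid"] += 1
        return f"g{counter['uid']:06d}"

    content: list[dict[str, list[str]]] = [dict() for _ in range(tree.n_nodes)]
    events = [BranchEvents(node=i) for i in range(tree.n_nodes)]
    content[tree.root] = {new_og(): [new_uid()] for _ in range(config.root_orthogroups)}

    for node in tree.preorder():
        if node == tree.root:
            continue
        parent_state = content[tree.parent[node]]
        length = lengths[node]
        state = {og: list(uids) for og, uids in parent_state.items()}
        ev = events[node]
        # irreversible losses
        p_loss = 1.0 - np.exp(-config.loss_rate * length)
        if p_loss > 0:
            ogs = list(state)
            lost = np.flatnonzero(rng.random(len(ogs)) < p_loss)
            for i in lost:
                og = ogs[i]
                ev.losses.append((og, tuple(state.pop(og))))
        # duplications in retained orthogroups
        if config.duplication_rate > 0 and state:
            ogs = list(state)
            n_dups = rng.poisson(config.duplication_rate * length, size=len(ogs))
            for og, k in zip(ogs, n_dups):
                for _ in range(int(k)):
                    parent_uid = state[og][int(rng.integers(len(state[og])))]
                    uid = new_uid()
                    state[og].append(uid)
                    ev.duplications.append((og, parent_uid, uid, None, None, "+"))
        # gains of brand-new orthogroups
        n_gains = int(rng.poisson(config.gain_rate * length))
        for _ in range(n_gains):
            og, uid = new_og(), new_uid()
            state[og] = [uid]
            ev.gains.append((og, uid, None, None))
        content[node] = state
    return content, events


def simulate_gene_content_fast(
    config: SimConfig, tree: RootedTree, rng: np.random.Generator
) -> tuple[OrthogroupMatrix, np.ndarray]:
    """Vectorised single-copy gene-content simulation (no duplications).

    Same Dollo model as :func:`simulate_gene_content` restricted to
    ``duplication_rate == 0``: per branch, gains ~ Poisson(gain_rate * len)
    and irreversible loss with probability 1 - exp(-loss_rate * len).  Used
    for large calibration studies (thousands of replicate matrices) where
    the per-gene event log is not needed.  Returns the tip copy-number
    matrix (0/1) and the full node x orthogroup presence array.
    """
    if config.duplication_rate != 0:
        raise ValueError("fast content path requires duplication_rate == 0")
    lengths = _branch_lengths(tree)
    n_nodes = tree.n_nodes
    gains = np.zeros(n_nodes, dtype=np.int64)
    gains[tree.root] = config.root_orthogroups
    for node in range(n_nodes):
        if node != tree.root:
            gains[node] = rng.poisson(config.gain_rate * lengths[node])
    n_og = int(gains.sum())
    origin = np.repeat(np.arange(n_nodes), gains)
    presence = np.zeros((n_nodes, n_og), dtype=bool)
    presence[tree.root] = origin == tree.root
    for node in tree.preorder():
        if node == tree.root:
            continue
        retain = rng.random(n_og) >= (1.0 - np.exp(-config.loss_rate * lengths[node]))
        presence[node] = (presence[tree.parent[node]] & retain) | (origin == node)
    taxa = sorted(tree.tips)
    counts = np.stack(
        [presence[tree.tip_index[t]] for t in taxa], axis=1
    ).astype(np.int64)
    og_ids = [f"OG{i + 1:05d}" for i in range(n_og)]
    return OrthogroupMatrix(og_ids, taxa, counts=counts), presence


def balanced_pair_tree(
    n_pairs: int, tip_length: float = 1.0, stem_length: float = 0.1
) -> str:
    """Newick for a caterpillar of marine/freshwater cherries (m<i>, f<i>).

    Within each cherry the two tips have equal branch lengths, so swapping
    the habitat labels of a pair is an exact symmetry of the generative
    model — the property the within-pair permutation test relies on.
    """
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    cherries = [
        f"(m{i}:{tip_length},f{i}:{tip_length}):{stem_length}"
        for i in range(1, n_pairs + 1)
    ]
    newick = cherries[0]
    for ch in cherries[1:-1]:
        newick = f"({newick},{ch}):{stem_length}"
    return f"({newick},{cherries[-1]});"


def plant_convergent_losses(
    content: list[dict[str, list[str]]],
    events: list[BranchEvents],
    tree: RootedTree,
    panel: HabitatPanel,
    n_planted: int,
    rng: np.random.Generator,
) -> list[str]:
    """Force ``n_planted`` orthogroups absent in every freshwater panel tip.

    Candidates must be present in every marine panel tip; the forced
    removals are logged as loss events on the freshwater terminal branches,
    so the event log stays replayable and the losses are real history.
    Returns the planted orthogroup ids.
    """
    marine_tips = [tree.tip_index[p.marine] for p in panel]
    fw_tips = [tree.tip_index[p.freshwater] for p in panel]
    candidates = sorted(
        og
        for og in content[marine_tips[0]]
        if all(og in content[t] for t in marine_tips)
    )
    if n_planted > len(candidates):
        raise ValueError(
            f"cannot plant {n_planted} convergent losses: only "
            f"{len(candidates)} orthogroups are present in all marine tips"
        )
    chosen = sorted(
        rng.choice(len(candidates), size=n_planted, replace=False).tolist()
    )
    planted = [candidates[i] for i in chosen]
    for og in planted:
        for t in fw_tips:
            if og in content[t]:
                events[t].losses.append((og, tuple(content[t].pop(og))))
    return planted


def simulate_gene_order(
    config: SimConfig,
    tree: RootedTree,
    content: list[dict[str, list[str]]],
    events: list[BranchEvents],
    rng: np.random.Generator,
) -> list[list[list[tuple[str, str, str]]]]:
    """Evolve ordered genomes consistent with the content event log.

    Genomes are lists of chromosomes; each chromosome is an ordered list of
    (uid, og, strand).  Placement choices (gain/duplicate positions,
    inversion and translocation intervals) are drawn here and written back
    into the event log so that replaying it reproduces every tip exactly.
    """
    lengths = _branch_lengths(tree)
    n_chrom = config.n_chromosomes
    root_genes = [(uid, og, "+") for og, uids in content[tree.root].items() for uid in uids]
    n_root = len(root_genes)
    bounds = np.linspace(0, n_root, n_chrom + 1).astype(int)
    genomes: list[list[list[tuple[str, str, str]]] | None] = [None] * tree.n_nodes
    genomes[tree.root] = [
        list(root_genes[bounds[c]:bounds[c + 1]]) for c in range(n_chrom)
    ]

    for node in tree.preorder():
        if node == tree.root:
            continue
        genome = [list(ch) for ch in genomes[tree.parent[node]]]
        ev = events[node]
        # losses: remove every copy of the lost orthogroup
        lost_uids = {u for _, uids in ev.losses for u in uids}
        if lost_uids:
            genome = [
                [g for g in ch if g[0] not in lost_uids] for ch in genome
            ]
        # duplications: insert next to the parent copy w.p. p_tandem, else uniformly
        for k, (og, parent_uid, uid, _, _, _) in enumerate(ev.duplications):
            pos = _find_uid(genome, parent_uid)
            if pos is not None and rng.random() < config.p_tandem:
                c, i = pos
                strand = genome[c][i][2]
                genome[c].insert(i + 1, (uid, og, strand))
                ev.duplications[k] = (og, parent_uid, uid, c, i + 1, strand)
            else:
                c = int(rng.integers(n_chrom))
                i = int(rng.integers(len(genome[c]) + 1))
                genome[c].insert(i, (uid, og, "+"))
                ev.duplications[k] = (og, parent_uid, uid, c, i, "+")
        # gains: uniform position on a uniform chromosome
        for k, (og, uid, _, _) in enumerate(ev.gains):
            c = int(rng.integers(n_chrom))
            i = int(rng.integers(len(genome[c]) + 1))
            genome[c].insert(i, (uid, og, "+"))
            ev.gains[k] = (og, uid, c, i)
        # inversions: reverse a uniform interval within one chromosome
        n_inv = int(rng.poisson(config.inversion_rate * lengths[node]))
        for _ in range(n_inv):
            c = int(rng.integers(n_chrom))
            size = len(genome[c])
            if size < 2:
                continue
            i, j = sorted(rng.integers(0, size + 1, size=2).tolist())
            if j - i < 2:
                continue
            genome[c][i:j] = [
                (u, og, _flip(s)) for (u, og, s) in reversed(genome[c][i:j])
            ]
            ev.inversions.append((c, i, j))
        # translocations: move a random segment to another chromosome
        n_tr = int(rng.poisson(config.translocation_rate * lengths[node]))
        for _ in range(n_tr):
            if n_chrom < 2:
                break
            src = int(rng.integers(n_chrom))
            size = len(genome[src])
            if size < 1:
                continue
            i, j = sorted(rng.integers(0, size + 1, size=2).tolist())
            if j == i:
                continue
            dst = int(rng.integers(n_chrom - 1))
            if dst >= src:
                dst += 1
            segment = genome[src][i:j]
            del genome[src][i:j]
            pos = int(rng.integers(len(genome[dst]) + 1))
            genome[dst][pos:pos] = segment
            ev.translocations.append((src, i, j, dst, pos))
        genomes[node] = genome
    return genomes  # type: ignore[return-value]


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _find_uid(genome, uid: str):
    for c, ch in enumerate(genome):
        for i, (u, _, _) in enumerate(ch):
            if u == uid:
                return c, i
    return None


def replay_events(
    tree: RootedTree,
    root_genome: list[list[tuple[str, str, str]]],
    events: list[BranchEvents],
) -> list[list[list[tuple[str, str, str]]]]:
    """Re-apply the event log from the root state; used to verify the log."""
    genomes: list = [None] * tree.n_nodes
    genomes[tree.root] = [list(ch) for ch in root_genome]
    for node in tree.preorder():
        if node == tree.root:
            continue
        genome = [list(ch) for ch in genomes[tree.parent[node]]]
        ev = events[node]
        lost_uids = {u for _, uids in ev.losses for u in uids}
        if lost_uids:
            genome = [[g for g in ch if g[0] not in lost_uids] for ch in genome]
        for og, parent_uid, uid, c, i, strand in ev.duplications:
            genome[c].insert(i, (uid, og, strand))
        for og, uid, c, i in ev.gains:
            genome[c].insert(i, (uid, og, "+"))
        for c, i, j in ev.inversions:
            genome[c][i:j] = [(u, og, _flip(s)) for (u, og, s) in reversed(genome[c][i:j])]
        for src, i, j, dst, pos in ev.translocations:
            segment = genome[src][i:j]
            del genome[src][i:j]
            genome[dst][pos:pos] = segment
        genomes[node] = genome
    return genomes


def observable_gain_loss(
    tree: RootedTree, content: list[dict[str, list[str]]]
) -> tuple[dict[str, int], dict[str, frozenset[int]]]:
    """Observable projection of the simulated history, per orthogroup.

    Computed by direct recursion on the simulator's own node states: the
    observable origin is reached by descending from the true gain node while
    only one child subtree retains surviving tips; observable losses are the
    maximal non-surviving subtrees hanging off surviving nodes.  Orthogroups
    retained in no tip are omitted (they are unobservable).
    """
    n = tree.n_nodes
    og_ids = sorted({og for state in content for og in state})
    origins: dict[str, int] = {}
    losses: dict[str, frozenset[int]] = {}
    for og in og_ids:
        surviving = np.zeros(n, dtype=bool)
        for v in tree.postorder():
            if tree.is_tip(v):
                surviving[v] = og in content[v]
            else:
                surviving[v] = any(surviving[c] for c in tree.children[v])
        # true gain node: shallowest node whose content holds the og
        gain_node = next(v for v in tree.preorder() if og in content[v])
        if not surviving[gain_node]:
            continue  # extinct everywhere: unobservable
        v = gain_node
        while not tree.is_tip(v):
            kids = [c for c in tree.children[v] if surviving[c]]
            if len(kids) != 1:
                break
            v = kids[0]
        origins[og] = v
        loss_children: list[int] = []
        stack = [v]
        while stack:
            u = stack.pop()
            for c in tree.children[u]:
                if surviving[c]:
                    stack.append(c)
                elif og in content[u]:
                    loss_children.append(c)
        losses[og] = frozenset(loss_children)
    return origins, losses


def _tip_matrix(tree: RootedTree, content) -> OrthogroupMatrix:
    taxa = sorted(tree.tips)
    og_ids = sorted({og for t in taxa for og in content[tree.tip_index[t]]})
    members = {
        og: {
            t: tuple(
                sorted(f"{t}_{u}" for u in content[tree.tip_index[t]].get(og, ()))
            )
            for t in taxa
            if content[tree.tip_index[t]].get(og)
        }
        for og in og_ids
    }
    return OrthogroupMatrix(og_ids, taxa, members=members)


def _tip_annotations(tree: RootedTree, genomes) -> dict[str, GenomeAnnotation]:
    out = {}
    for taxon, node in tree.tip_index.items():
        records = []
        for c, chrom in enumerate(genomes[node]):
            for rank, (uid, og, strand) in enumerate(chrom):
                records.append(
                    (f"chr{c + 1}", rank * 1000, rank * 1000 + 500, f"{taxon}_{uid}", strand)
                )
        out[taxon] = GenomeAnnotation.from_records(taxon, records)
    return out


def simulate_dataset(config: SimConfig) -> SimResult:
    """Run the full simulation pipeline described by one config."""
    rng = np.random.default_rng(config.seed)
    tree = RootedTree.from_newick(config.tree)
    content, events = simulate_gene_content(config, tree, rng)
    planted: list[str] = []
    if config.planted_convergent_losses > 0:
        if not config.panel:
            raise ValueError("planting convergent losses requires a habitat panel")
        panel = HabitatPanel(config.panel)
        planted = plant_convergent_losses(
            content, events, tree, panel, config.planted_convergent_losses, rng
        )
    genomes = None
    annotations: dict[str, GenomeAnnotation] = {}
    if config.simulate_order:
        genomes = simulate_gene_order(config, tree, content, events, rng)
        annotations = _tip_annotations(tree, genomes)
    matrix = _tip_matrix(tree, content)
    truth_origin, truth_losses = observable_gain_loss(tree, content)
    return SimResult(
        config=config,
        tree=tree,
        content=content,
        events=events,
        matrix=matrix,
        genomes=genomes,
        annotations=annotations,
        planted_losses=planted,
        truth_origin=truth_origin,
        truth_losses=truth_losses,
    )


def _pair_hits(
    result: SimResult, taxon_a: str, taxon_b: str, rng: np.random.Generator
) -> tuple[list[SimilarityHit], list[SimilarityHit]]:
    """Mutual similarity rows A->B and B->A for one species pair, degraded."""
    config = result.config
    tree = result.tree
    ca = result.content[tree.tip_index[taxon_a]]
    cb = result.content[tree.tip_index[taxon_b]]
    ab: list[SimilarityHit] = []
    ba: list[SimilarityHit] = []
    for og in sorted(set(ca) & set(cb)):
        for ua in ca[og]:
            for ub in cb[og]:
                base = ORTHOLOG_BASE if ua == ub else PARALOG_BASE
                score = base - round(float(rng.random()), 3)
                ga, gb = f"{taxon_a}_{ua}", f"{taxon_b}_{ub}"
                ab.append(SimilarityHit(ga, gb, 1e-50, score))
                ba.append(SimilarityHit(gb, ga, 1e-50, score))

    def degrade(hits: list[SimilarityHit], genes_q: list[str], genes_s: list[str]):
        if config.similarity_dropout > 0 and hits:
            keep = rng.random(len(hits)) >= config.similarity_dropout
            hits = [h for h, k in zip(hits, keep) if k]
        if config.spurious_hit_rate > 0 and genes_q and genes_s:
            n_spur = int(rng.binomial(max(len(hits), 1), config.spurious_hit_rate))
            for _ in range(n_spur):
                q = genes_q[int(rng.integers(len(genes_q)))]
                s = genes_s[int(rng.integers(len(genes_s)))]
                hits.append(
                    SimilarityHit(q, s, 1e-5, SPURIOUS_BASE - round(float(rng.random()), 3))
                )
        return hits

    genes_a = sorted(f"{taxon_a}_{u}" for us in ca.values() for u in us)
    genes_b = sorted(f"{taxon_b}_{u}" for us in cb.values() for u in us)
    return degrade(ab, genes_a, genes_b), degrade(ba, genes_b, genes_a)


def _self_hits(
    result: SimResult, taxon: str, rng: np.random.Generator
) -> list[SimilarityHit]:
    """Within-species paralog hits (both orientations) for tandem/dotplot analyses."""
    c = result.content[result.tree.tip_index[taxon]]
    hits: list[SimilarityHit] = []
    for og in sorted(c):
        uids = c[og]
        for i in range(len(uids)):
            for j in range(i + 1, len(uids)):
                score = PARALOG_BASE + 50.0 - round(float(rng.random()), 3)
                gi, gj = f"{taxon}_{uids[i]}", f"{taxon}_{uids[j]}"
                hits.append(SimilarityHit(gi, gj, 1e-40, score))
                hits.append(SimilarityHit(gj, gi, 1e-40, score))
    return hits


def similarity_tables(result: SimResult) -> dict[tuple[str, str], list[SimilarityHit]]:
    """All pairwise (directed) and self similarity tables, deterministically seeded."""
    rng = np.random.default_rng(np.random.SeedSequence([result.config.seed, 7]))
    taxa = sorted(result.tree.tips)
    out: dict[tuple[str, str], list[SimilarityHit]] = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            ab, ba = _pair_hits(result, a, b, rng)
            out[(a, b)] = ab
            out[(b, a)] = ba
    for t in taxa:
        out[(t, t)] = _self_hits(result, t, rng)
    return out


def emit_dataset(result: SimResult, outdir) -> dict:
    """Write the whole fixture directory; returns the manifest (also saved as truth.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = result.tree
    taxa = sorted(tree.tips)
    with open(outdir / "tree.nwk", "w") as fh:
        fh.write(tree.to_newick() + "\n")
    for taxon, annot in sorted(result.annotations.items()):
        write_annotation(annot, outdir / f"{taxon}.bed")
    write_orthogroups(result.matrix, outdir / "Orthogroups.tsv")
    tables = similarity_tables(result)
    for (a, b), hits in sorted(tables.items()):
        name = f"{a}__self.tsv" if a == b else f"{a}__vs__{b}.tsv"
        write_similarity_table(hits, outdir / name)
    if result.config.panel:
        with open(outdir / "panel.tsv", "w") as fh:
            fh.write("phylum\tmarine_taxon\tfreshwater_taxon\n")
            for phylum, marine, fresh in result.config.panel:
                fh.write(f"{phylum}\t{marine}\t{fresh}\n")
    origins, losses = result.truth_per_node()
    truth = {
        "config": result.config.to_dict(),
        "seed": result.config.seed,
        "taxa": taxa,
        "n_orthogroups": len(result.matrix.orthogroup_ids),
        "planted_convergent_losses": result.planted_losses,
        "observable_origins_per_node": origins.tolist(),
        "observable_losses_per_node": losses.tolist(),
        "node_labels": list(tree.labels),
        "events_per_branch": {
            str(ev.node): {
                "gains": len(ev.gains),
                "losses": len(ev.losses),
                "duplications": len(ev.duplications),
                "inversions": len(ev.inversions),
                "translocations": len(ev.translocations),
            }
            for ev in result.events
        },
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
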