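# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of the `synteloss` package.

## Data model and conventions

Gene positions are reduced to **ordinal ranks**: within each scaffold,
genes are numbered 0..n−1 by ascending start coordinate, ties broken by
(end, gene_id) so loading is deterministic. BED input is treated as 0-based
half-open; GFF3 (only `gene` features, identified by their `ID` attribute)
is 1-based inclusive and converted on load. Gene identity across files is
exact string equality — no prefix stripping — because silent identifier
munging is a classic source of spurious or missing synteny. A validation
step reports the symmetric difference of taxon names between the
orthogroup matrix, the tree and the habitat panel before any analysis runs.

Similarity input is the 12-column BLAST tabular dialect; only query,
subject, e-value and bitscore are consumed. Malformed rows fail hard with
their line number: these tables are typically machine-generated, and a
wrong column count means the wrong file, not a recoverable blemish.

## Reciprocal best hits

Multiple HSP rows per (query, subject) collapse to the max-bitscore row
(ties by smaller e-value). A query's best subject is decided by bitscore,
then e-value; if its top two *distinct* subjects still tie, the gene is
ambiguous and excluded from the pairing rather than resolved arbitrarily —
an arbitrarily resolved tie would inject a random dot into the Oxford grid.
Bitscore (not e-value) is the primary key by default because e-values
saturate at 0 for strong hits; both keys are applied in order anyway.

## Macrosynteny

The enrichment universe is **ortholog pairs**, not genes: `n_total` counts
pairs with both members annotated, and scaffold margins are pair counts
over that same universe. A cell's p-value is the exact upper hypergeometric
tail (scipy implementation; verified against exact rational enumeration to
≤ 1e-12 for all populations ≤ 20). BH correction is scoped per species
pair over non-empty cells, matching how one grid is read at a time.

Classification defaults: `q_max = 0.05`, `min_pairs = 5`,
`colinear_min = 0.8`. No published thresholds exist for this procedure, so
the defaults are explicit, configurable, and echoed into the run report.
Spearman's ρ is undefined (and not computed) below 3 pairs; classification
then rests on `lis_fraction` alone. `lis_fraction` takes the *longest
strictly monotone* subsequence in either direction, so a single whole-arm
inversion — biologically still perfectly co-linear — scores 1. It is
computed by patience sorting (O(n log n)) and is invariant under global
reversal of either axis.

Tandem arrays are maximal same-family runs on one scaffold with at most
`max_gap` intervening genes (default 0) between consecutive members; gene
families come from single-linkage clustering of within-species hits at a
configurable bitscore floor (default 50 — again an explicit choice, not an
inherited one). The self-dotplot emits one point per within-scaffold hit
plus its mirror, oriented forward when strands agree.

## Dollo reconstruction

Presence/absence of each orthogroup is reconstructed under Dollo parsimony:
a single origin at the MRCA of the present tips, losses on exactly the
edges from a retaining node to a non-retaining child inside the origin's
subtree. This is the unique minimal single-gain explanation; the test suite
proves the implementation equal to exhaustive minimal-assignment search for
every rooted topology with ≤ 6 tips and every presence pattern. Polytomies
are allowed; losses attribute per child edge. Orthogroups absent from every
analysis taxon carry no placement information and are dropped with a
counted warning. Summaries are keyed by clade tip-sets and are therefore
invariant to Newick rotation.

Tip "gene gains" are reported under **two definitions**, both emitted:
(i) orthogroup-level — orthogroups whose origin is the terminal edge;
(ii) gene-level — member genes of those tip-born orthogroups plus the
copy-number excess (count − 1) in older orthogroups still present. A
single-number "genes gained" figure depends on which definition is meant,
so the package refuses to choose silently.

The topology contrast runs the same reconstruction under two root
hypotheses with the same tip set and reports per-clade deltas for clades
present in both trees.

## Convergent loss

The default lineage-loss definition requires presence only in the paired
counterpart (an orthogroup present in the marine member, absent in the
freshwater member); a stricter flag additionally requires presence outside
the pair. Both are exposed because the natural-language definition
("losses specific to freshwater species") underdetermines the rule.

All four t-test variants are always reported. The within-pair permutation
test swaps marine/freshwater labels over all 2ⁿ assignments (exact mode;
Monte-Carlo with a recorded seed otherwise) and counts the identity
assignment, so p ≥ 1/2ⁿ by construction. The default statistic is the
difference in mean leave-one-out intersection counts, which is less
degenerate than the full n-way intersection when n grows. Background
shared-absence enumerates subsets exactly while C(#taxa, size) ≤ 10,000
and samples with a seed beyond that.

**Calibration note.** With a 4-pair panel the exact test cannot reject at
α = 0.05 (minimum p is 1/16 = 0.0625); the calibration study therefore
uses 6 pairs, where the attainable rejection rate at 0.05 is 3/64 ≈ 0.047.
Null panels are simulated on a tree of six cherries with equal within-pair
branch lengths — label swapping is then an exact symmetry of the model —
with terminal loss probability 1 − e^(−λ) = 0.5 and 12,000 root
orthogroups, chosen so leave-one-out intersections have mean ≈ 10 and the
discrete statistic rarely ties. The suite checks the empirical rejection
rate over 1000 replicates lies in [0.03, 0.07].

## The simulator

`simulate_dataset` evolves gene content on a rooted tree under a strict
Dollo regime (no regain, so reconstruction is exact rather than
approximate): per branch of length ℓ, new orthogroups arise as
Poisson(γℓ), each existing orthogroup dies with probability 1 − e^(−λℓ),
and each retained orthogroup gains Poisson(δℓ) copies. Gene order evolves
by within-chromosome inversions (Poisson(ρ_inv ℓ); a uniform interval is
reversed and member strands flip) and between-chromosome translocations
(Poisson(ρ_tr ℓ); a uniform segment moves to a uniform position elsewhere)
— chromosome membership is conserved when ρ_tr = 0, which is exactly the
DCJ-DS regime the synteny classifier is meant to detect. Duplicates insert
adjacent to their parent copy with probability `p_tandem` (default 0.7),
seeding tandem arrays.

Similarity tables contain a mutual hit for every within-orthogroup gene
pair: true orthologous copies (same ancestral gene) score around 200,
paralogous copies around 100, with a small seeded jitter breaking ties;
tables are then degraded by per-row dropout and spurious random hits
(default rates 0). Planted convergent losses are implemented as forced
loss events on the freshwater terminal branches, so the event log remains
replayable and the planted losses are genuine history, not post-hoc matrix
edits.

One `numpy` Generator seeded from the config drives every draw: identical
configs give byte-identical emitted files. The event log records placement
choices, and replaying it from the root state must reproduce every tip
genome exactly (checked in the tests).

Two truth channels are recorded. Raw events are what happened; the
**observable projection** (origin at the MRCA of surviving tips, losses as
maximal extinct subtrees) is what any method restricted to tip data can
recover — two sibling losses collapse into one observable loss, and a gain
whose sibling subtree goes extinct shifts the observable origin tipward.
Recovery tests compare against the observable projection, which the
simulator computes by direct per-character recursion on its own node
states, independent of the vectorised reconstruction code.

A vectorised single-copy content path (`simulate_gene_content_fast`,
duplications disabled) implements the same model for calibration studies
that need thousands of replicate matrices.

### What the simulator does and does not emulate

It reproduces the statistical structure the analyses assume: Dollo-like
content evolution, within-chromosome shuffling with rare translocations,
tandem-biased duplication, similarity dropout and noise, planted
convergent losses. It does **not** simulate sequences (bitscores are
stylised, not alignment-derived), gene conversion, orthogroup re-gain,
assembly fragmentation, annotation error beyond dropout, or realistic
branch-length heterogeneity. Passing tests therefore demonstrate
correctness of the inference machinery under its own model assumptions —
not robustness to the full messiness of real annotations, which should be
assessed per dataset (the dropout/spurious-hit knobs are a first probe).

## Problem sizes

Default study sizes used by the tests and the acceptance script: 200
random table pairs (≤ 50 genes/side) for the RBH oracle; all hypergeometric
margins with population ≤ 20; all 1,069 rooted topologies with ≤ 6 tips ×
all presence patterns (63,039 reconstructions); 10 replicate 8-tip
histories (γ = 5, λ = 0.3, 500 root orthogroups) for gain/loss recovery;
20 seeds × 4 inversion levels (0/5/20/100) on 3 × 200-gene genomes for the
synteny sweep; 1000 null panels for permutation calibration. The whole
acceptance run completes in well under a minute on one CPU.

## Known limitations

* RBH orthology is one-to-one; paralog-rich families are delegated to the
  orthogroup matrix, and RBH recovery on simulated data is exact only when
  duplication is off.
* The hypergeometric test treats ortholog pairs as exchangeable across the
  grid; very long scaffolds with many pairs violate independence mildly,
  which BH across cells does not repair. The labels are a screen, not a
  posterior.
* Dollo is an assumption, not an inference: horizontally transferred or
  re-gained families will be misplaced by construction.
* The exact permutation test is limited to ~20 pairs (2ⁿ assignments);
  beyond that use the seeded Monte-Carlo mode.
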