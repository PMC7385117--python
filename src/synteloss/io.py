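"""Domain types and readers/writers for the standard comparative-genomics formats.

Covers gene annotations (BED4+, GFF3 ``gene`` features), BLAST tabular
similarity tables (12-column outfmt-6 dialect), OrthoFinder-style
``Orthogroups.tsv`` copy-number matrices, and Newick trees (via
:mod:`synteloss.trees`).

Coordinate conventions: BED is 0-based half-open; GFF3 is 1-based inclusive
and is converted to 0-based half-open on load.  Within each scaffold genes
get ordinal ranks 0..n-1 by ascending start, ties broken by (end, gene_id).
Gene identity is exact string match everywhere — no prefix stripping.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .trees import RootedTree, TreeError, load_tree, reroot

__all__ = [
    "FormatError",
    "DataWarning",
    "GeneLocus",
    "GenomeAnnotation",
    "SimilarityHit",
    "OrthogroupMatrix",
    "load_annotation",
    "write_annotation",
    "load_similarity_table",
    "write_similarity_table",
    "load_orthogroups",
    "write_orthogroups",
    "load_tree",
    "reroot",
    "load_habitat_panel",
    "validate_taxon_names",
]


class FormatError(ValueError):
    """A file violates the named format's contract."""


class DataWarning(UserWarning):
    """Recoverable data oddities (kept, but reported)."""


VALID_STRANDS = ("+", "-", "?")


@dataclass(frozen=True)
class GeneLocus:
    """One gene on one scaffold: ordinal rank plus bp coordinates (0-based, half-open)."""

    gene_id: str
    species_id: str
    scaffold_id: str
    rank: int
    start: int
    end: int
    strand: str = "?"


class GenomeAnnotation:
    """Ordered gene lists per scaffold for one species.

    ``scaffolds`` maps scaffold_id -> list of :class:`GeneLocus` sorted by
    rank; every gene id occurs exactly once in the whole annotation.
    """

    def __init__(self, species_id: str, scaffolds: dict[str, list[GeneLocus]]):
        self.species_id = species_id
        self.scaffolds = scaffolds
        self._locus: dict[str, GeneLocus] = {}
        for scaf, loci in scaffolds.items():
            for locus in loci:
                if locus.gene_id in self._locus:
                    raise FormatError(
                        f"duplicate gene id {locus.gene_id!r} in {species_id}"
                    )
                self._locus[locus.gene_id] = locus

    @classmethod
    def from_records(
        cls,
        species_id: str,
        records: Iterable[tuple[str, int, int, str, str]],
    ) -> "GenomeAnnotation":
        """Build from (scaffold, start, end, gene_id, strand) tuples, assigning ranks."""
        by_scaffold: dict[str, list[tuple[str, int, int, str, str]]] = {}
        for rec in records:
            by_scaffold.setdefault(rec[0], []).append(rec)
        scaffolds: dict[str, list[GeneLocus]] = {}
        for scaf in sorted(by_scaffold):
            rows = sorted(by_scaffold[scaf], key=lambda r: (r[1], r[2], r[3]))
            scaffolds[scaf] = [
                GeneLocus(gene_id=g, species_id=species_id, scaffold_id=scaf,
                          rank=i, start=s, end=e, strand=st)
                for i, (scaf_, s, e, g, st) in enumerate(rows)
            ]
        return cls(species_id, scaffolds)

    @property
    def gene_ids(self) -> list[str]:
        return list(self._locus)

    @property
    def n_genes(self) -> int:
        return len(self._locus)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._locus

    def locus(self, gene_id: str) -> GeneLocus:
        return self._locus[gene_id]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenomeAnnotation)
            and self.species_id == other.species_id
            and self.scaffolds == other.scaffolds
        )


class SimilarityHit(NamedTuple):
    """One row of a similarity search: query, subject, e-value, bitscore."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float


class OrthogroupMatrix:
    """Orthogroups x taxa copy-number matrix with optional gene membership lists."""

    def __init__(
        self,
        orthogroup_ids: Sequence[str],
        taxa: Sequence[str],
        counts: np.ndarray | None = None,
        members: dict[str, dict[str, tuple[str, ...]]] | None = None,
    ):
        self.orthogroup_ids = list(orthogroup_ids)
        self.taxa = list(taxa)
        if len(set(self.orthogroup_ids)) != len(self.orthogroup_ids):
            raise FormatError("duplicate orthogroup ids")
        self.og_index = {o: i for i, o in enumerate(self.orthogroup_ids)}
        self.taxon_index = {t: j for j, t in enumerate(self.taxa)}
        if members is not None:
            counts = np.zeros((len(self.orthogroup_ids), len(self.taxa)), dtype=np.int64)
            for og, per_taxon in members.items():
                for taxon, genes in per_taxon.items():
                    counts[self.og_index[og], self.taxon_index[taxon]] = len(genes)
        elif counts is None:
            raise ValueError("need counts or members")
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (len(self.orthogroup_ids), len(self.taxa)):
            raise ValueError("counts shape does not match ids/taxa")
        if (counts < 0).any():
            raise ValueError("negative copy numbers")
        self.counts = counts
        self.members = members

    def presence(self) -> np.ndarray:
        """Binary presence view: True where copy number >= 1."""
        return self.counts >= 1

    def members_of(self, og: str, taxon: str) -> tuple[str, ...]:
        if self.members is None:
            raise ValueError("matrix carries no membership lists")
        return self.members.get(og, {}).get(taxon, ())

    def presence_of(self, og: str) -> frozenset[str]:
        """Taxa in which orthogroup ``og`` is present."""
        row = self.counts[self.og_index[og]]
        return frozenset(t for t, j in self.taxon_index.items() if row[j] >= 1)


# ----------------------------------------------------------------------
# annotations


def _parse_bed(path: Path, species_id: str):
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(f"{path}:{lineno}: BED needs >=4 columns, got {len(cols)}")
            scaf, start, end, gene = cols[0], cols[1], cols[2], cols[3]
            if not scaf:
                raise FormatError(f"{path}:{lineno}: feature without scaffold")
            strand = cols[5] if len(cols) >= 6 and cols[5] in ("+", "-") else "?"
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            records.append((scaf, s, e, gene, strand))
    return records


def _gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = value.strip()
    return out


def _parse_gff3(path: Path, species_id: str):
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 needs 9 columns, got {len(cols)}")
            scaf, _, ftype, start, end, _, strand, _, attrs = cols
            if ftype != "gene":
                continue
            if not scaf or scaf == ".":
                raise FormatError(f"{path}:{lineno}: gene feature without scaffold")
            gene = _gff3_attributes(attrs).get("ID")
            if not gene:
                raise FormatError(f"{path}:{lineno}: gene feature lacks an ID attribute")
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            # GFF3 is 1-based inclusive -> 0-based half-open
            records.append((scaf, s - 1, e, gene, strand if strand in ("+", "-") else "?"))
    return records


def load_annotation(path, fmt: str | None = None, species_id: str | None = None) -> GenomeAnnotation:
    """Load gene positions from BED or GFF3 and assign within-scaffold ranks.

    ``fmt`` is ``"bed"`` or ``"gff3"``; inferred from the file suffix when
    omitted.  Duplicate gene ids are a hard error.
    """
    path = Path(path)
    if species_id is None:
        species_id = path.stem
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "gff3" if suffix in (".gff", ".gff3") else "bed"
    if fmt == "bed":
        records = _parse_bed(path, species_id)
    elif fmt == "gff3":
        records = _parse_gff3(path, species_id)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    return GenomeAnnotation.from_records(species_id, records)


def write_annotation(annot: GenomeAnnotation, path) -> None:
    """Write an annotation as BED6 (round-trips through :func:`load_annotation`)."""
    with open(path, "w") as fh:
        for scaf in annot.scaffolds:
            for locus in annot.scaffolds[scaf]:
                strand = locus.strand if locus.strand in ("+", "-") else "."
                fh.write(
                    f"{scaf}\t{locus.start}\t{locus.end}\t{locus.gene_id}\t0\t{strand}\n"
                )


# ----------------------------------------------------------------------
# similarity tables


def load_similarity_table(path) -> list[SimilarityHit]:
    """Parse a 12-column BLAST outfmt-6 table (query, subject, ..., evalue, bitscore)."""
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(cols)}"
                )
            try:
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric evalue/bitscore"
                ) from exc
            if not np.isfinite(bitscore) or evalue < 0:
                raise FormatError(f"{path}:{lineno}: invalid evalue/bitscore")
            hits.append(SimilarityHit(cols[0], cols[1], evalue, bitscore))
    return hits


def write_similarity_table(hits: Iterable[SimilarityHit], path) -> None:
    """Write hits in the 12-column outfmt-6 dialect (unused columns zeroed)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t100.0\t0\t0\t0\t0\t0\t0\t0\t"
                f"{h.evalue:g}\t{h.bitscore:g}\n"
            )


# ----------------------------------------------------------------------
# orthogroup matrices


def load_orthogroups(path) -> OrthogroupMatrix:
    """Parse an OrthoFinder-style Orthogroups.tsv into an :class:`OrthogroupMatrix`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file (no header)")
        head_cols = header.split("\t")
        if head_cols[0] != "Orthogroup":
            raise FormatError(f"{path}: header must start with 'Orthogroup'")
        taxa = head_cols[1:]
        og_ids: list[str] = []
        members: dict[str, dict[str, tuple[str, ...]]] = {}
        seen_gene_taxon: dict[str, str] = {}
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != len(head_cols):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(head_cols)} columns, got {len(cols)}"
                )
            og = cols[0]
            if og in members:
                raise FormatError(f"{path}:{lineno}: duplicated orthogroup id {og!r}")
            og_ids.append(og)
            row: dict[str, tuple[str, ...]] = {}
            for taxon, cell in zip(taxa, cols[1:]):
                genes = tuple(g.strip() for g in cell.split(",") if g.strip())
                row[taxon] = genes
                for g in genes:
                    prev = seen_gene_taxon.get(g)
                    if prev is not None and prev != taxon:
                        warnings.warn(
                            f"gene {g!r} listed under both {prev!r} and {taxon!r}",
                            DataWarning,
                        )
                    seen_gene_taxon[g] = taxon
            members[og] = row
    return OrthogroupMatrix(og_ids, taxa, members=members)


def write_orthogroups(matrix: OrthogroupMatrix, path) -> None:
    """Write an Orthogroups.tsv (round-trips when membership lists are present)."""
    if matrix.members is None:
        raise ValueError("cannot write an Orthogroups.tsv without membership lists")
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(matrix.taxa) + "\n")
        for og in matrix.orthogroup_ids:
            cells = [", ".join(matrix.members_of(og, t)) for t in matrix.taxa]
            fh.write(og + "\t" + "\t".join(cells) + "\n")


# ----------------------------------------------------------------------
# habitat panels & validation


def load_habitat_panel(path) -> list[tuple[str, str, str]]:
    """Read a (phylum, marine_taxon, freshwater_taxon) TSV with header."""
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["phylum", "marine_taxon", "freshwater_taxon"]:
            raise FormatError(
                f"{path}: header must be phylum<TAB>marine_taxon<TAB>freshwater_taxon"
            )
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            rows.append((cols[0], cols[1], cols[2]))
    return rows


def validate_taxon_names(
    matrix_taxa: Iterable[str],
    tree_taxa: Iterable[str] | None = None,
    panel_taxa: Iterable[str] | None = None,
    strict: bool = True,
) -> dict[str, list[str]]:
    """Report exact-name mismatches between matrix, tree and habitat panel.

    Returns the symmetric differences; with ``strict`` (default) any
    mismatch raises :class:`FormatError` before an analysis can run on
    silently misaligned taxa.
    """
    m = set(matrix_taxa)
    report: dict[str, list[str]] = {}
    if tree_taxa is not None:
        t = set(tree_taxa)
        report["matrix_not_tree"] = sorted(m - t)
        report["tree_not_matrix"] = sorted(t - m)
    if panel_taxa is not None:
        p = set(panel_taxa)
        report["panel_not_matrix"] = sorted(p - m)
    if strict and any(report.get(k) for k in ("matrix_not_tree", "panel_not_matrix")):
        raise FormatError(f"taxon name mismatch: {report}")
    return report
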