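"""Readers and writers for the plain-text formats the pipeline consumes.

Formats: FASTA (CDS/protein), a BED-like gene-position table (TSV with
columns species, chromosome, start, end, strand, gene_id), tabular homology
pairs (12-column BLAST outfmt-6 or a minimal 4-column TSV), newick trees
with numeric branch supports, 2-column gene->TF-family and gene->GO tables,
and an optional child->parent GO edge table.

All readers reject malformed records rather than repairing them, and every
write/read pair round-trips to identity.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A record violates the documented format contract."""


@dataclass
class GeneModel:
    """A gene: identity, location as a rank along its chromosome, and CDS.

    ``rank`` is the 0-based order of the gene along its chromosome by
    ascending start coordinate, ignoring strand.  ``cds`` may be empty for
    position-only stubs; when present its length is a multiple of 3 and it
    contains only ACGTN.
    """

    gene_id: str
    species: str
    chromosome: str
    rank: int
    cds: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.cds:
            if len(self.cds) % 3 != 0:
                raise FormatError(
                    f"CDS length of {self.gene_id} is {len(self.cds)}, not a multiple of 3"
                )
            if set(self.cds) - set("ACGTN"):
                raise FormatError(f"CDS of {self.gene_id} contains non-ACGTN characters")


@dataclass(frozen=True)
class HomologyPair:
    """One homologous gene pair from an all-vs-all similarity search."""

    gene_a: str
    gene_b: str
    evalue: float
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise FormatError(f"self-pair {self.gene_a}")
        if self.evalue < 0:
            raise FormatError(f"negative evalue for ({self.gene_a}, {self.gene_b})")

    @property
    def key(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an order-preserving id -> sequence mapping.

    The id is the header token before the first whitespace.  Duplicate ids
    and empty sequences are errors.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for {rec.id!r} in {path}")
        out[rec.id] = seq
    if not out:
        raise FormatError(f"no FASTA records in {path}")
    return out


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Gene positions

POSITION_COLUMNS = ("species", "chromosome", "start", "end", "strand", "gene_id")


def read_gene_positions(path: str | Path) -> list[GeneModel]:
    """Read the gene-position TSV and assign per-chromosome ranks.

    Genes are ranked within each (species, chromosome) by ascending start,
    ties broken by gene_id; coordinates are 0-based half-open.  Two rows
    with the same gene_id are an error.
    """
    rows: list[tuple[str, str, int, int, str, str]] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != POSITION_COLUMNS:
            raise FormatError(
                f"gene-position table must have columns {POSITION_COLUMNS}, got {tuple(header)}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            species, chrom, start, end, strand, gene_id = parts
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            rows.append((species, chrom, int(start), int(end), strand, gene_id))
    genes: list[GeneModel] = []
    by_chrom: dict[tuple[str, str], list[tuple[int, str, int, str]]] = {}
    for species, chrom, start, end, strand, gene_id in rows:
        by_chrom.setdefault((species, chrom), []).append((start, gene_id, end, strand))
    for (species, chrom), items in by_chrom.items():
        items.sort(key=lambda t: (t[0], t[1]))
        for rank, (start, gene_id, end, strand) in enumerate(items):
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    species=species,
                    chromosome=chrom,
                    rank=rank,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
    return genes


def write_gene_positions(path: str | Path, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(POSITION_COLUMNS) + "\n")
        for g in genes:
            fh.write(
                f"{g.species}\t{g.chromosome}\t{g.start}\t{g.end}\t{g.strand}\t{g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Homology pairs

def read_homology_pairs(path: str | Path) -> list[HomologyPair]:
    """Read homology pairs from 12-column outfmt-6-like or 4-column TSV.

    Only gene_a, gene_b, evalue and bitscore are retained.  In the
    12-column layout those are columns 1, 2, 11, 12.
    """
    pairs: list[HomologyPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 12:
                a, b, ev, bs = parts[0], parts[1], parts[10], parts[11]
            elif len(parts) == 4:
                a, b, ev, bs = parts
            else:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 or 12 columns, got {len(parts)}"
                )
            pairs.append(HomologyPair(a, b, float(ev), float(bs)))
    return pairs


def write_homology_pairs(path: str | Path, pairs: Iterable[HomologyPair]) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.evalue:.3g}\t{p.bitscore:.1f}\n")


# ---------------------------------------------------------------------------
# Trees

SPECIES_DELIMITER = "|"


def _normalise_supports(tree: dendropy.Tree) -> None:
    # percent-scale supports (values > 1) are divided by 100
    for node in tree.preorder_internal_node_iter():
        if node.label is None or node.label == "":
            continue
        try:
            value = float(node.label)
        except ValueError as exc:
            raise FormatError(f"unparseable support label {node.label!r}") from exc
        if value > 1.0:
            value /= 100.0
        if not 0.0 <= value <= 1.0:
            raise FormatError(f"support {value} outside [0, 1] after normalization")
        node.label = f"{value:g}"


def parse_tree(newick: str) -> dendropy.Tree:
    """Parse one rooted newick string with leaf labels ``species|gene_id``.

    Internal-node labels are supports; values above 1 are treated as
    percentages and rescaled to [0, 1].
    """
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"unparseable newick: {exc}") from exc
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else None
        if label is None or SPECIES_DELIMITER not in label:
            raise FormatError(
                f"leaf {label!r} lacks the '{SPECIES_DELIMITER}' species delimiter"
            )
    _normalise_supports(tree)
    return tree


def read_tree(path: str | Path) -> dendropy.Tree:
    return parse_tree(Path(path).read_text())


def write_tree(path: str | Path, tree: dendropy.Tree) -> None:
    Path(path).write_text(tree_to_newick(tree) + "\n")


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def read_gene_trees(path: str | Path) -> dict[str, dendropy.Tree]:
    """Read a 2-column TSV of orthogroup_id -> newick."""
    trees: dict[str, dendropy.Tree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            og, newick = parts
            if og in trees:
                raise FormatError(f"{path}:{lineno}: duplicate orthogroup id {og!r}")
            trees[og] = parse_tree(newick)
    return trees


def write_gene_trees(path: str | Path, trees: Mapping[str, dendropy.Tree | str]) -> None:
    with open(path, "w") as fh:
        for og, tree in trees.items():
            nwk = tree if isinstance(tree, str) else tree_to_newick(tree)
            fh.write(f"{og}\t{nwk.strip()}\n")


def leaf_species(label: str) -> str:
    return label.split(SPECIES_DELIMITER, 1)[0]


def leaf_gene(label: str) -> str:
    return label.split(SPECIES_DELIMITER, 1)[1]


# ---------------------------------------------------------------------------
# Two-column annotation tables

def _read_two_column(path: str | Path, what: str) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns in {what} table")
            rows.append((parts[0], parts[1]))
    return rows


def read_tf_families(path: str | Path) -> dict[str, str]:
    """Read the gene -> TF-family table; conflicting rows are errors."""
    table: dict[str, str] = {}
    for gene, family in _read_two_column(path, "TF-family"):
        if gene in table and table[gene] != family:
            raise FormatError(
                f"gene {gene!r} assigned to both {table[gene]!r} and {family!r}"
            )
        table[gene] = family
    return table


def write_tf_families(path: str | Path, table: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for gene, family in table.items():
            fh.write(f"{gene}\t{family}\n")


def read_go_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read the one-row-per-annotation gene -> GO-term table."""
    table: dict[str, set[str]] = {}
    for gene, term in _read_two_column(path, "GO"):
        table.setdefault(gene, set()).add(term)
    return table


def write_go_annotations(path: str | Path, table: Mapping[str, Iterable[str]]) -> None:
    with open(path, "w") as fh:
        for gene, terms in table.items():
            for term in sorted(terms):
                fh.write(f"{gene}\t{term}\n")


def read_go_edges(path: str | Path) -> list[tuple[str, str]]:
    """Read the child -> parent GO edge table."""
    return _read_two_column(path, "GO-edge")


def write_go_edges(path: str | Path, edges: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for child, parent in edges:
            fh.write(f"{child}\t{parent}\n")


def read_orthogroups(path: str | Path) -> dict[str, dict[str, list[str]]]:
    """Read the long-format orthogroup TSV (orthogroup, species, gene_id)."""
    out: dict[str, dict[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            og, species, gene = parts
            out.setdefault(og, {}).setdefault(species, []).append(gene)
    return out


def write_orthogroups(path: str | Path, groups: Mapping[str, Mapping[str, list[str]]]) -> None:
    with open(path, "w") as fh:
        for og in groups:
            for species in groups[og]:
                for gene in groups[og][species]:
                    fh.write(f"{og}\t{species}\t{gene}\n")
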