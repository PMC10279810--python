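"""Readers and writers for the formats the pipeline touches.

Sequences travel as plain ``dict[str, str]`` keyed by record id (insertion
order preserved).  Trees are :class:`RootedTree`, a thin wrapper around a
dendropy tree that enforces the contracts the rest of the package relies on
(unique leaf labels, non-negative branch lengths, an explicit root).
Genome annotations are tab-delimited feature tables normalised to 0-based
half-open circular coordinates.

All readers reject malformed input rather than silently repairing it; every
writer produces output its paired reader accepts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import FormatError

__all__ = [
    "read_fasta",
    "write_fasta",
    "RootedTree",
    "read_newick",
    "write_newick",
    "GeneFeature",
    "GenomeLayout",
    "read_annotations",
    "write_annotations",
    "circular_midpoint",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Case is preserved verbatim.  Duplicate ids and empty files are format
    errors; the record id is the full header line (everything after ``>``)
    stripped of surrounding whitespace.
    """
    records: dict[str, str] = {}
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            name = header.strip()
            if name in records:
                raise FormatError(f"duplicate FASTA id {name!r} in {path}")
            records[name] = seq
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: dict[str, str], path) -> None:
    """Write sequences one record per line-pair (no line wrapping)."""
    with open(path, "w") as handle:
        for name, seq in records.items():
            handle.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

@dataclass
class RootedTree:
    """A rooted phylogeny with branch lengths in expected substitutions
    per (nucleotide) site.

    Wraps a :class:`dendropy.Tree`; validation happens at construction so
    downstream code can assume unique leaf labels and non-negative lengths.
    """

    tree: dendropy.Tree

    def __post_init__(self):
        labels = [leaf.taxon.label if leaf.taxon else None
                  for leaf in self.tree.leaf_node_iter()]
        if any(lab is None or lab == "" for lab in labels):
            raise FormatError("tree contains an unlabeled leaf")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise FormatError(f"duplicate leaf labels: {dupes}")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise FormatError(f"negative branch length {edge.length}")

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, allow_missing_lengths: bool = False
                    ) -> "RootedTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True)
        except Exception as exc:
            raise FormatError(f"cannot parse Newick: {exc}") from exc
        missing = [e for e in tree.preorder_edge_iter()
                   if e.length is None and e.head_node is not tree.seed_node]
        if missing:
            if not allow_missing_lengths:
                raise FormatError(
                    "tree has edges without branch lengths; pass "
                    "allow_missing_lengths=True to default them to 0")
            for e in missing:
                e.length = 0.0
        return cls(tree)

    # -- properties ---------------------------------------------------------
    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def n_edges(self) -> int:
        return sum(1 for n in self.tree.preorder_node_iter()
                   if n is not self.tree.seed_node)

    @property
    def total_length(self) -> float:
        return sum(e.length or 0.0 for e in self.tree.preorder_edge_iter())

    def to_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick", suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".12g").strip()
        return s

    def clone(self) -> "RootedTree":
        return RootedTree(self.tree.clone(depth=1))


def read_newick(path, allow_missing_lengths: bool = False) -> RootedTree:
    """Read a single rooted tree from a Newick file."""
    text = Path(path).read_text().strip()
    if not text:
        raise FormatError(f"empty Newick file: {path}")
    if text.count(";") > 1:
        raise FormatError(f"expected a single tree in {path}")
    return RootedTree.from_newick(text, allow_missing_lengths)


def write_newick(tree: RootedTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Genome annotations
# ---------------------------------------------------------------------------

def circular_midpoint(start: int, end: int, genome_length: int) -> int:
    """Midpoint of a circular 0-based half-open interval.

    ``end <= start`` denotes a feature wrapping the origin.  The midpoint is
    ``floor((start + end') / 2) mod L`` with ``end'`` unwrapped, so a
    half-integer centre rounds down, e.g. (10, 100) on a 1000 nt circle
    gives 55 and the wrapping feature (990, 10) gives 0.
    """
    if not (0 <= start < genome_length):
        raise FormatError(f"start {start} outside [0, {genome_length})")
    if not (0 < end <= genome_length):
        raise FormatError(f"end {end} outside (0, {genome_length}]")
    end_unwrapped = end if end > start else end + genome_length
    return ((start + end_unwrapped) // 2) % genome_length


@dataclass
class GeneFeature:
    """A gene on a circular genome; 0-based half-open, ``end <= start``
    means the feature wraps the origin."""

    gene_id: str
    start: int
    end: int
    strand: str = "+"

    def span(self, genome_length: int) -> int:
        end = self.end if self.end > self.start else self.end + genome_length
        return end - self.start

    def midpoint(self, genome_length: int) -> int:
        return circular_midpoint(self.start, self.end, genome_length)


@dataclass
class GenomeLayout:
    """Circular genome coordinates of genes and inverted-repeat borders
    for one species."""

    species: str
    genome_length: int
    ir_a: tuple[int, int] | None = None
    ir_b: tuple[int, int] | None = None
    genes: dict[str, GeneFeature] = field(default_factory=dict)

    def midpoint(self, gene_id: str) -> int:
        return self.genes[gene_id].midpoint(self.genome_length)


_ANNOT_COLUMNS = ["species", "feature", "type", "start", "end", "strand",
                  "genome_length"]


def read_annotations(path) -> dict[str, GenomeLayout]:
    """Read a tab-delimited feature table into per-species layouts.

    Columns: species, feature, type (``gene`` or ``IR``), start, end,
    strand, genome_length.  Coordinates are 0-based half-open on the
    circle; ``end < start`` wraps the origin.  IR rows must be named
    ``IRa``/``IRb``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "feature": str,
                                            "type": str, "strand": str})
    missing = [c for c in _ANNOT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation table missing columns {missing}")
    layouts: dict[str, GenomeLayout] = {}
    for row in df.itertuples(index=False):
        L = int(row.genome_length)
        start, end = int(row.start), int(row.end)
        if start < 0 or start >= L:
            raise FormatError(
                f"feature {row.feature}: start {start} outside [0, {L})")
        if end <= 0 or end > L:
            raise FormatError(
                f"feature {row.feature}: end {end} outside (0, {L}]")
        layout = layouts.setdefault(
            row.species, GenomeLayout(species=row.species, genome_length=L))
        if layout.genome_length != L:
            raise FormatError(
                f"inconsistent genome_length for species {row.species}")
        if row.type == "IR":
            if row.feature == "IRa":
                layout.ir_a = (start, end)
            elif row.feature == "IRb":
                layout.ir_b = (start, end)
            else:
                raise FormatError(f"IR feature must be IRa or IRb, got "
                                  f"{row.feature!r}")
        elif row.type == "gene":
            if row.feature in layout.genes:
                raise FormatError(f"duplicate gene {row.feature!r} for "
                                  f"species {row.species}")
            layout.genes[row.feature] = GeneFeature(
                gene_id=row.feature, start=start, end=end,
                strand=str(row.strand))
        else:
            raise FormatError(f"unknown feature type {row.type!r}")
    return layouts


def write_annotations(layouts: dict[str, GenomeLayout], path) -> None:
    rows = []
    for layout in layouts.values():
        for name, iv in (("IRa", layout.ir_a), ("IRb", layout.ir_b)):
            if iv is not None:
                rows.append((layout.species, name, "IR", iv[0], iv[1], "+",
                             layout.genome_length))
        for g in layout.genes.values():
            rows.append((layout.species, g.gene_id, "gene", g.start, g.end,
                         g.strand, layout.genome_length))
    pd.DataFrame(rows, columns=_ANNOT_COLUMNS).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Minimal TOML writing (reading uses stdlib tomllib)
# ---------------------------------------------------------------------------

def dump_toml(mapping: dict, path) -> None:
    """Serialise a flat-ish mapping (scalars, lists of scalars, one level of
    sub-tables) as TOML.  Sufficient for config echoes."""

    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, (int, float)):
            return repr(v)
        if isinstance(v, str):
            return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
        if isinstance(v, (list, tuple)):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        raise TypeError(f"cannot serialise {type(v)} to TOML")

    buf = io.StringIO()
    tables = {k: v for k, v in mapping.items() if isinstance(v, dict)}
    for k, v in mapping.items():
        if not isinstance(v, dict) and v is not None:
            buf.write(f"{k} = {fmt(v)}\n")
    for name, tab in tables.items():
        buf.write(f"\n[{name}]\n")
        for k, v in tab.items():
            if v is not None:
                buf.write(f"{k} = {fmt(v)}\n")
    Path(path).write_text(buf.getvalue())
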