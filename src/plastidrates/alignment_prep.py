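"""Codon-alignment construction and cleaning.

Codon alignments are built by threading each coding sequence onto its
aligned protein (back-translation), so the nucleotide alignment can never
disagree with the protein alignment.  Columns dominated by gaps are then
removed at the codon level, keeping the reading frame intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .errors import DataError

__all__ = [
    "CodonAlignment",
    "back_translate",
    "trim_gap_columns",
    "concatenate",
]

GAP_CODON = "---"
_DNA = set("ACGT")


def _codon_table(table_id: int = 1) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[table_id]


def _is_ambiguous(codon: str) -> bool:
    """A codon counts as missing if any position is a gap or non-ACGT."""
    return any(c not in _DNA for c in codon.upper())


@dataclass
class CodonAlignment:
    """A gap-aware codon matrix for one gene.

    Every cell is either the gap triplet ``---`` or a codon; internal stop
    codons are forbidden.  Codons containing ambiguity characters (N, X,
    ...) are tolerated and treated as missing data downstream.
    """

    gene_id: str
    sequences: dict[str, str]
    genetic_code: int = 1
    gene_boundaries: list[tuple[str, int, int]] = field(default_factory=list)
    """Per-gene codon-column provenance after concatenation:
    (gene_id, first_column, last_column_exclusive)."""

    def __post_init__(self):
        if not self.sequences:
            raise DataError(f"{self.gene_id}: empty alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise DataError(f"{self.gene_id}: unequal sequence lengths "
                            f"{sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise DataError(f"{self.gene_id}: length {length} not a "
                            "multiple of 3")
        stops = _codon_table(self.genetic_code).stop_codons
        for sp, seq in self.sequences.items():
            for j in range(0, length, 3):
                codon = seq[j:j + 3].upper()
                if codon in stops:
                    raise DataError(
                        f"{self.gene_id}/{sp}: internal stop codon {codon} "
                        f"at codon column {j // 3}")
        if not self.gene_boundaries:
            self.gene_boundaries = [(self.gene_id, 0, self.n_codons)]

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.sequences.values()))) // 3

    def codon(self, species: str, column: int) -> str:
        return self.sequences[species][3 * column:3 * column + 3]

    def column_gap_fraction(self, column: int) -> float:
        n_gap = sum(_is_ambiguous(self.codon(sp, column))
                    for sp in self.sequences)
        return n_gap / len(self.sequences)


# ---------------------------------------------------------------------------
# Back-translation (protein alignment + CDS -> codon alignment)
# ---------------------------------------------------------------------------

def _translate_cds(cds: str, table_id: int) -> str:
    if len(cds) % 3 != 0:
        raise DataError(f"CDS length {len(cds)} is not a multiple of 3")
    return str(Seq(cds).translate(table=table_id))


def back_translate(protein_alignment: dict[str, str],
                   cds_sequences: dict[str, str],
                   genetic_code: int = 1,
                   gene_id: str = "gene") -> CodonAlignment:
    """Thread CDS codons onto an aligned protein, producing a codon
    alignment whose translation is exactly the input protein alignment.

    A terminal stop codon on the CDS is stripped before matching.  An
    annotated non-ATG start is accepted: the first translated residue is
    compared as M.  Any other mismatch between the ungapped protein and the
    CDS translation is an error reporting species, column and residues.
    """
    missing = set(protein_alignment) ^ set(cds_sequences)
    if missing:
        raise DataError(f"{gene_id}: species present on only one side of "
                        f"the back-translation: {sorted(missing)}")
    stops = _codon_table(genetic_code).stop_codons
    out: dict[str, str] = {}
    for sp, prot in protein_alignment.items():
        cds = cds_sequences[sp]
        if len(cds) >= 3 and cds[-3:].upper() in stops:
            cds = cds[:-3]
        translated = _translate_cds(cds, genetic_code)
        if translated:
            translated = "M" + translated[1:]
        ungapped = prot.replace("-", "")
        if ungapped:
            ungapped = "M" + ungapped[1:]
        if len(translated) != len(ungapped):
            raise DataError(
                f"{gene_id}/{sp}: protein length {len(ungapped)} does not "
                f"match CDS translation length {len(translated)}")
        codons = []
        k = 0
        for col, residue in enumerate(prot):
            if residue == "-":
                codons.append(GAP_CODON)
                continue
            expect = "M" if k == 0 else residue.upper()
            observed = translated[k]
            if expect not in ("X", observed):
                raise DataError(
                    f"{gene_id}/{sp}: translation mismatch at alignment "
                    f"column {col}: expected {expect!r}, observed "
                    f"{observed!r}")
            codons.append(cds[3 * k:3 * k + 3])
            k += 1
        out[sp] = "".join(codons)
    return CodonAlignment(gene_id=gene_id, sequences=out,
                          genetic_code=genetic_code)


# ---------------------------------------------------------------------------
# Trimming and concatenation
# ---------------------------------------------------------------------------

def trim_gap_columns(alignment: CodonAlignment,
                     max_gap_fraction: float = 0.9
                     ) -> tuple[CodonAlignment, list[tuple[int, float]]]:
    """Drop codon columns whose gap fraction strictly exceeds
    ``max_gap_fraction`` (default: columns with >90% gaps).

    Ambiguous codons count as gaps for the trimming statistic.  Returns the
    trimmed alignment and a report of ``(removed_column, gap_fraction)``
    pairs in the original column numbering.
    """
    removed: list[tuple[int, float]] = []
    kept: list[int] = []
    for col in range(alignment.n_codons):
        frac = alignment.column_gap_fraction(col)
        if frac > max_gap_fraction:
            removed.append((col, frac))
        else:
            kept.append(col)
    if not kept:
        raise DataError(f"{alignment.gene_id}: trimming removed every "
                        "column")
    sequences = {
        sp: "".join(alignment.codon(sp, c) for c in kept)
        for sp in alignment.sequences
    }
    trimmed = CodonAlignment(gene_id=alignment.gene_id, sequences=sequences,
                             genetic_code=alignment.genetic_code)
    return trimmed, removed


def concatenate(alignments: list[CodonAlignment]) -> CodonAlignment:
    """Concatenate gene alignments sharing an identical species set,
    recording per-gene column provenance."""
    if not alignments:
        raise DataError("nothing to concatenate")
    if len(alignments) == 1:
        return alignments[0]
    species = set(alignments[0].species)
    for aln in alignments[1:]:
        if set(aln.species) != species:
            diff = sorted(set(aln.species) ^ species)
            raise DataError(f"species sets differ between genes; "
                            f"non-shared species: {diff}")
    order = alignments[0].species
    sequences = {sp: "".join(a.sequences[sp] for a in alignments)
                 for sp in order}
    boundaries = []
    offset = 0
    for a in alignments:
        boundaries.append((a.gene_id, offset, offset + a.n_codons))
        offset += a.n_codons
    return CodonAlignment(
        gene_id="+".join(a.gene_id for a in alignments),
        sequences=sequences,
        genetic_code=alignments[0].genetic_code,
        gene_boundaries=boundaries)
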