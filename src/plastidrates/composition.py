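"""Sequence-composition covariates.

Two per-gene summaries:

* **Substitution tolerance** — BLOSUM62 half-bit log-odds scores are
  back-calculated to odds ratios (o_ab = 2^(s_ab/2)); each residue gets a
  tolerance T_a equal to the geometric mean of its odds of substitution to
  the 19 other standard residues; a gene's score is the arithmetic mean of
  T over the concatenation of its protein sequences across all species.
  Lower scores mark compositions less tolerant of amino-acid replacement.

* **GC3 / GC12** — G+C fraction at third codon positions, excluding
  methionine (ATG) and tryptophan (TGG) codons (no third-position freedom),
  plus gap/stop/ambiguous codons; GC12 analogously over positions 1-2
  without the Met/Trp exclusion.
"""

from __future__ import annotations

import functools
import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .alignment_prep import CodonAlignment
from .errors import DataError, FormatError

__all__ = [
    "RESIDUES",
    "SubstitutionMatrix",
    "load_blosum62",
    "read_matrix",
    "back_calculate_odds",
    "residue_tolerance",
    "tolerance_table",
    "protein_tolerance_score",
    "GC3Result",
    "gc3",
]

RESIDUES = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric integer log-odds scores (half-bit units) over the 20
    standard amino acids."""

    residues: str
    scores: np.ndarray        # 20x20, integer-valued

    def __post_init__(self):
        if self.scores.shape != (len(self.residues),) * 2:
            raise FormatError("score matrix shape does not match alphabet")
        if not np.array_equal(self.scores, self.scores.T):
            raise FormatError("substitution matrix must be symmetric")

    def score(self, a: str, b: str) -> float:
        return float(self.scores[self.residues.index(a),
                                 self.residues.index(b)])


def read_matrix(path) -> SubstitutionMatrix:
    """Read an NCBI-style substitution matrix text file (comment lines
    start with '#'; first non-comment line is the column alphabet)."""
    residues: str | None = None
    rows: dict[str, list[int]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if residues is None:
                residues = "".join(fields)
                continue
            rows[fields[0]] = [int(x) for x in fields[1:]]
    if residues is None or not rows:
        raise FormatError(f"no matrix found in {path}")
    missing = [a for a in residues if a not in rows]
    if missing:
        raise FormatError(f"matrix rows missing for {missing}")
    scores = np.array([rows[a] for a in residues], dtype=float)
    return SubstitutionMatrix(residues=residues, scores=scores)


def load_blosum62() -> SubstitutionMatrix:
    """The packaged standard BLOSUM62 matrix (20 residues; B/Z/X and stop
    columns excluded)."""
    ref = importlib.resources.files("plastidrates.data") / "blosum62.txt"
    with importlib.resources.as_file(ref) as path:
        return read_matrix(path)


# ---------------------------------------------------------------------------
# Tolerance scores
# ---------------------------------------------------------------------------

def back_calculate_odds(matrix: SubstitutionMatrix) -> np.ndarray:
    """Invert the half-bit log-odds convention: o_ab = 2^(s_ab / 2)."""
    return np.exp2(matrix.scores / 2.0)


def residue_tolerance(odds: np.ndarray, residue: str,
                      residues: str = RESIDUES) -> float:
    """Geometric mean of a residue's substitution odds to the other 19
    standard residues (the diagonal/self term is excluded)."""
    if residue not in residues:
        raise DataError(f"unknown residue {residue!r}")
    i = residues.index(residue)
    off = np.delete(odds[i], i)
    return float(np.exp(np.mean(np.log(off))))


@functools.lru_cache(maxsize=1)
def _default_tolerance_table() -> dict[str, float]:
    matrix = load_blosum62()
    odds = back_calculate_odds(matrix)
    return {a: residue_tolerance(odds, a, matrix.residues)
            for a in matrix.residues}


def tolerance_table(matrix: SubstitutionMatrix | None = None
                    ) -> dict[str, float]:
    """Per-residue tolerance T_a for every standard residue."""
    if matrix is None:
        return dict(_default_tolerance_table())
    odds = back_calculate_odds(matrix)
    return {a: residue_tolerance(odds, a, matrix.residues)
            for a in matrix.residues}


def protein_tolerance_score(sequences: dict[str, str],
                            matrix: SubstitutionMatrix | None = None
                            ) -> float:
    """Mean per-residue tolerance over the concatenation of a gene's
    protein sequences across species.

    Gap and ambiguity characters (-, X, ...) are excluded from both
    numerator and denominator, so the score is invariant to alignment
    padding and to how the concatenation is partitioned.
    """
    tol = tolerance_table(matrix)
    total = 0.0
    count = 0
    for seq in sequences.values():
        for ch in seq.upper():
            t = tol.get(ch)
            if t is not None:
                total += t
                count += 1
    if count == 0:
        raise DataError("no scoreable residues (all gaps/ambiguity)")
    return total / count


# ---------------------------------------------------------------------------
# GC3 / GC12
# ---------------------------------------------------------------------------

@dataclass
class GC3Result:
    gene_id: str
    per_species: dict[str, float]
    gc3_mean: float
    gc12_per_species: dict[str, float]
    gc12_mean: float


_DNA = set("ACGT")


def _included_codons(seq: str, stops: set[str], exclude_met_trp: bool):
    for j in range(0, len(seq), 3):
        codon = seq[j:j + 3].upper()
        if any(c not in _DNA for c in codon):
            continue
        if codon in stops:
            continue
        if exclude_met_trp and codon in ("ATG", "TGG"):
            continue
        yield codon


def gc3(alignment: CodonAlignment) -> GC3Result:
    """Per-species GC3 (Met/Trp, gap, stop and ambiguous codons excluded)
    and GC12 (same exclusions except Met/Trp); the gene-level value is the
    unweighted mean across species."""
    stops = set(CodonTable.unambiguous_dna_by_id[
        alignment.genetic_code].stop_codons)
    per3: dict[str, float] = {}
    per12: dict[str, float] = {}
    for sp, seq in alignment.sequences.items():
        codons3 = list(_included_codons(seq, stops, exclude_met_trp=True))
        if not codons3:
            raise DataError(f"{alignment.gene_id}/{sp}: no codons usable "
                            "for GC3 (all Met/Trp/gap/ambiguous)")
        per3[sp] = sum(c[2] in "GC" for c in codons3) / len(codons3)
        codons12 = list(_included_codons(seq, stops, exclude_met_trp=False))
        per12[sp] = (sum((c[0] in "GC") + (c[1] in "GC") for c in codons12)
                     / (2 * len(codons12)))
    return GC3Result(
        gene_id=alignment.gene_id,
        per_species=per3,
        gc3_mean=float(np.mean(list(per3.values()))),
        gc12_per_species=per12,
        gc12_mean=float(np.mean(list(per12.values()))))


def composition_table(alignments: list[CodonAlignment],
                      matrix: SubstitutionMatrix | None = None
                      ) -> pd.DataFrame:
    """Per-gene composition covariates: substitution tolerance (computed on
    the translated, ungapped codon sequences) and mean GC3/GC12."""
    from Bio.Seq import Seq

    rows = []
    for aln in alignments:
        proteins = {
            sp: str(Seq(seq.replace("-", "")).translate(
                table=aln.genetic_code))
            for sp, seq in aln.sequences.items()
        }
        g = gc3(aln)
        rows.append((aln.gene_id,
                     protein_tolerance_score(proteins, matrix),
                     g.gc3_mean,
                     g.gc12_mean))
    return pd.DataFrame(rows, columns=["gene", "tolerance_score",
                                       "gc3_mean", "gc12_mean"])
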