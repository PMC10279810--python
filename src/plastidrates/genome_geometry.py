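"""Plastome geometry: inverted-repeat detection and gene-position
covariates.

A quadripartite plastid genome carries two large reverse-complement copies
(IRa, IRb) separating the large and small single-copy regions.  The
detector anchors k-mers of the genome against its reverse complement and
greedily extends each anchor on the circle, returning the longest pair of
disjoint intervals whose sequences are reverse complements (optionally
allowing a mismatch fraction).  Gene position is summarised as the
circular-arc distance from the gene midpoint to the nearer border of the
single-copy region that contains it — the paper-facing covariate is the
cross-species mean of that distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError, DataError
from .io_formats import GenomeLayout

__all__ = [
    "revcomp",
    "IRPair",
    "detect_inverted_repeat",
    "distance_to_ir",
    "average_gene_distance",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IRPair:
    """A detected inverted-repeat pair: two disjoint 0-based half-open
    circular intervals with sequence(ir_b) = revcomp(sequence(ir_a))."""

    ir_a: tuple[int, int]
    ir_b: tuple[int, int]
    length: int
    mismatches: int


def _interval_seq(seq: str, start: int, end: int) -> str:
    L = len(seq)
    if end > start:
        return seq[start:end]
    return seq[start:] + seq[:end]


def detect_inverted_repeat(genome_sequence: str, min_length: int = 1000,
                           max_mismatch_fraction: float = 0.0,
                           k: int = 21) -> IRPair | None:
    """Find the largest inverted-repeat pair on a circular sequence.

    Anchoring: every k-mer of the genome is matched against the k-mers of
    its reverse complement; each anchor is extended greedily in both
    directions on the circle while the running mismatch fraction stays
    within ``max_mismatch_fraction`` (exact matching by default).
    Non-ACGT characters never match.  Returns ``None`` when no pair of
    disjoint intervals of at least ``min_length`` exists.  Tie-break:
    longest pair, then smallest start coordinate of its first interval.
    """
    if min_length < 50:
        raise ConfigError("min_length must be >= 50")
    if k < 8 or k > min_length:
        raise ConfigError("anchor size k must be in [8, min_length]")
    seq = genome_sequence.upper()
    L = len(seq)
    if L < 2 * min_length:
        return None
    comp = seq.translate(_COMPLEMENT)

    def base(i: int) -> str:
        return seq[i % L]

    def cbase(i: int) -> str:
        return comp[i % L]

    # k-mer index of the genome (circular: wrap k-1 characters)
    doubled = seq + seq[:k - 1]
    kmer_pos: dict[str, list[int]] = {}
    for i in range(L):
        kmer = doubled[i:i + k]
        if set(kmer) <= set("ACGT"):
            kmer_pos.setdefault(kmer, []).append(i)

    allowed = max_mismatch_fraction
    seen: set[tuple[int, int]] = set()
    best: IRPair | None = None

    for i in range(L):
        kmer = doubled[i:i + k]
        hits = kmer_pos.get(revcomp(kmer))
        if not hits:
            continue
        for j in hits:
            # seq[i:i+k] == revcomp(seq[j:j+k]): positions i+m pair with
            # j+k-1-m.  Extend the pairing (i+m <-> j2-m) with j2 = j+k-1.
            j2 = j + k - 1
            # canonical anchor key: midpoint sum is invariant under
            # extension, so one key per maximal pair per (i+j2) diagonal
            key = ((i + j2) % (2 * L), (i - j2) % 2)
            if key in seen:
                continue
            seen.add(key)
            # extend right on i / left on j2 side
            lo, hi = 0, k - 1          # offsets m in [lo-?, hi]
            mism = 0
            length = k
            # extend forward: m = hi+1 pairs base(i+m) with cbase(j2-m)...
            while length < L // 2:
                m = hi + 1
                a, b = base(i + m), cbase(j2 - m)
                if a in "ACGT" and a == b:
                    hi = m
                    length += 1
                elif allowed > 0 and (mism + 1) / (length + 1) <= allowed:
                    hi = m
                    mism += 1
                    length += 1
                else:
                    break
            while length < L // 2:
                m = lo - 1
                a, b = base(i + m), cbase(j2 - m)
                if a in "ACGT" and a == b:
                    lo = m
                    length += 1
                elif allowed > 0 and (mism + 1) / (length + 1) <= allowed:
                    lo = m
                    mism += 1
                    length += 1
                else:
                    break
            if length < min_length:
                continue
            a_start = (i + lo) % L
            b_start = (j2 - hi) % L
            # disjointness on the circle
            if _overlap(a_start, length, b_start, length, L):
                continue
            pair = _canonical_pair(a_start, b_start, length, L, mism)
            if best is None or (pair.length, -_norm_start(pair)) > (
                    best.length, -_norm_start(best)):
                best = pair
    return best


def _norm_start(pair: IRPair) -> int:
    return pair.ir_a[0]


def _canonical_pair(a_start: int, b_start: int, length: int, L: int,
                    mism: int) -> IRPair:
    def interval(start):
        end = start + length
        return (start, end if end <= L else end % L)   # end in (0, L]

    first, second = sorted([interval(a_start), interval(b_start)])
    return IRPair(ir_a=first, ir_b=second, length=length, mismatches=mism)


def _overlap(s1: int, len1: int, s2: int, len2: int, L: int) -> bool:
    """Do two circular intervals intersect?"""
    for off in range(2):
        a0 = s1 if off == 0 else s2
        l0 = len1 if off == 0 else len2
        b0 = s2 if off == 0 else s1
        l1 = len2 if off == 0 else len1
        # does b0 fall inside [a0, a0+l0)?
        if (b0 - a0) % L < l0:
            return True
    return False


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _sc_region_for(midpoint: int, ir_a: tuple[int, int],
                   ir_b: tuple[int, int], L: int
                   ) -> tuple[int, int] | None:
    """The single-copy region (as a circular half-open interval between IR
    borders) containing the midpoint, or None if the midpoint lies in an
    IR."""
    regions = [(ir_a[1], ir_b[0]), (ir_b[1], ir_a[0])]
    for start, end in regions:
        if (midpoint - start) % L < (end - start) % L:
            return (start, end)
    return None


def distance_to_ir(layout: GenomeLayout, gene_id: str) -> int:
    """Circular-arc distance (nt) from a gene's midpoint to the closest
    border of the single-copy region containing it.

    IR borders are the boundary coordinates of the half-open IR intervals;
    genes overlapping an IR are an error (only single-copy genes are
    analysed).
    """
    if layout.ir_a is None or layout.ir_b is None:
        raise DataError(f"{layout.species}: IR intervals unknown")
    L = layout.genome_length
    gene = layout.genes[gene_id]
    mid = gene.midpoint(L)
    region = _sc_region_for(mid, layout.ir_a, layout.ir_b, L)
    if region is None:
        raise DataError(f"{layout.species}/{gene_id}: midpoint {mid} lies "
                        "inside an inverted repeat")
    # the whole gene must sit in a single-copy region
    span = gene.span(L)
    for iv in (layout.ir_a, layout.ir_b):
        ir_len = (iv[1] - iv[0]) % L or L
        if _overlap(gene.start, span, iv[0], ir_len, L):
            raise DataError(f"{layout.species}/{gene_id}: gene overlaps an "
                            "inverted repeat")
    start, end = region
    return int(min((mid - start) % L, (end - mid) % L))


def average_gene_distance(layouts: dict[str, GenomeLayout]) -> pd.DataFrame:
    """Cross-species mean distance to the nearest IR border, per gene.

    Every gene must be present in every species (the analysis set is the
    ubiquitous single-copy genes).  Returns a table (gene, mean_distance,
    n_species) sorted by gene id; per-species distances are in
    ``df.attrs['per_species']``.
    """
    if not layouts:
        raise DataError("no layouts supplied")
    gene_sets = {sp: set(l.genes) for sp, l in layouts.items()}
    all_genes = set.union(*gene_sets.values())
    missing = {g: [sp for sp, gs in gene_sets.items() if g not in gs]
               for g in all_genes}
    missing = {g: sps for g, sps in missing.items() if sps}
    if missing:
        raise DataError(f"genes missing in some species: {missing}")
    per_species_rows = []
    for sp, layout in layouts.items():
        for g in sorted(all_genes):
            per_species_rows.append((g, sp, distance_to_ir(layout, g)))
    per = pd.DataFrame(per_species_rows,
                       columns=["gene", "species", "distance"])
    out = (per.groupby("gene", as_index=False)
           .agg(mean_distance=("distance", "mean"),
                n_species=("distance", "size")))
    out.attrs["per_species"] = per
    return out
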