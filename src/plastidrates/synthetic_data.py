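"""Synthetic plastome cohorts with planted effects.

The generator emulates the study design the pipeline is built for: a set of
species related by a shared rooted topology, each with a circular
quadripartite genome (two exact inverted repeats separating a large and a
small single-copy region), carrying the same single-copy genes; per-gene
codon alignments simulated under MG94xREV+F3X4 with gene-specific rate
multipliers and omega values.  Rate multipliers are planted on covariates:

    log mu_g = beta_distance * z(d_g) + beta_mrna * z(log m_g) + eps_g,
    eps_g ~ Normal(0, noise_sd^2)

where d_g is the gene's cross-species mean distance to the nearest
inverted-repeat border and m_g its (log-normal) mRNA abundance.  The truth
table stores mu, omega, the covariates, their z-scores and the noise draw,
so every downstream estimate can be checked against known truth.

Everything is a pure function of (config, seed): identical configs produce
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import codon_model, genome_geometry
from .alignment_prep import CodonAlignment
from .errors import ConfigError
from .io_formats import (GeneFeature, GenomeLayout, RootedTree, dump_toml,
                         write_annotations, write_fasta, write_newick)

__all__ = [
    "SyntheticConfig",
    "Cohort",
    "generate_species_tree",
    "generate_layouts",
    "simulate_cohort",
    "generate_cohort",
    "write_cohort",
]

ENERGY = "energy production"
INFO = "information processing"


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a small angiosperm-like plastome panel: 16 species,
    40 single-copy genes of 300 codons on a 150 kb circular genome with two
    exact 25 kb inverted repeats, a root-to-tip height of 0.1 expected
    substitutions per nucleotide site (plastid genes evolve slowly), and
    negative planted effects of both distance-to-IR and mRNA abundance on
    the gene rate multiplier.
    """

    n_species: int = 16
    n_genes: int = 40
    codons_per_gene: int | tuple[int, ...] = 300
    genome_length: int = 150_000
    ir_length: int = 25_000
    tree_height: float = 0.1
    beta_distance: float = -0.5
    beta_mrna: float = -0.5
    omega_range: tuple[float, float] = (0.05, 0.5)
    noise_sd: float = 0.1
    seed: int = 0
    # secondary knobs
    mrna_meanlog: float = 2.0
    mrna_sdlog: float = 1.0
    covariate_correlation: float = 0.0   # corr(z(d), z(log m)); 0 = none
    position_jitter: int = 500           # per-species jitter of gene starts
    freq_base: tuple[float, ...] = (0.3, 0.2, 0.2, 0.3)  # AT-rich plastome
    freq_concentration: float = 30.0     # Dirichlet concentration per gene
    protein_missing_fraction: float = 0.2
    protein_noise_sdlog: float = 0.5
    energy_fraction: float = 0.6

    def __post_init__(self):
        if self.n_species < 3:
            raise ConfigError("n_species must be >= 3")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        codons = self.codons_list()
        if len(codons) != self.n_genes:
            raise ConfigError("codons_per_gene must be scalar or one value "
                              "per gene")
        if min(codons) < 10:
            raise ConfigError("codons_per_gene must be >= 10")
        if self.ir_length < 1:
            raise ConfigError("quadripartite structure requires "
                              "ir_length >= 1")
        if 2 * self.ir_length + self.total_gene_span > self.genome_length:
            raise ConfigError(
                "geometry does not fit: 2*ir_length + total gene span "
                f"({2 * self.ir_length + self.total_gene_span}) exceeds "
                f"genome_length ({self.genome_length})")
        lo, hi = self.omega_range
        if not (0 < lo <= hi <= 1):
            raise ConfigError("omega_range must lie within (0, 1]")
        if self.tree_height <= 0:
            raise ConfigError("tree_height must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not -1 < self.covariate_correlation < 1:
            raise ConfigError("covariate_correlation must be in (-1, 1)")

    def codons_list(self) -> list[int]:
        if isinstance(self.codons_per_gene, int):
            return [self.codons_per_gene] * self.n_genes
        return list(self.codons_per_gene)

    @property
    def total_gene_span(self) -> int:
        return sum(3 * c for c in self.codons_list())

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"gene{str(i + 1).zfill(width)}"
                for i in range(self.n_genes)]

    @property
    def species_ids(self) -> list[str]:
        width = len(str(self.n_species))
        return [f"sp{str(i + 1).zfill(width)}"
                for i in range(self.n_species)]

    def as_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out


def _gene_seed(seed: int, g: int) -> int:
    # fixed per-gene offsets keep gene streams reproducible under reordering
    return (seed * 100_003 + 7_919 * (g + 1)) % (2 ** 31)


# ---------------------------------------------------------------------------
# Species tree (Yule topology, ultrametric, rescaled height)
# ---------------------------------------------------------------------------

def generate_species_tree(config: SyntheticConfig) -> RootedTree:
    """Pure-birth (Yule) rooted binary tree with exponential waiting times,
    rescaled so the root-to-tip height equals ``tree_height``."""
    rng = np.random.default_rng(_gene_seed(config.seed, -1) % (2 ** 31))
    n = config.n_species
    # active lineages: (birth_time, subtree-as-nested-list)
    active: list[tuple[float, object]] = [(0.0, 0), (0.0, 1)]
    parents: dict[int, tuple[int, int]] = {}
    birth = {0: 0.0, 1: 0.0}
    next_id = 2
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        _, node = active.pop(idx)
        a, b = next_id, next_id + 1
        next_id += 2
        parents[node] = (a, b)
        birth[a] = birth[b] = t
        active.append((t, a))
        active.append((t, b))
    height = t + rng.exponential(1.0 / n)
    scale = config.tree_height / height

    labels = iter(config.species_ids)

    def newick(node: int, parent_birth: float) -> str:
        length = ((height if node not in parents else _split_time(node))
                  - birth[node]) * scale
        if node in parents:
            a, b = parents[node]
            inner = f"({newick(a, 0)},{newick(b, 0)})"
            return f"{inner}:{length:.12g}"
        return f"{next(labels)}:{length:.12g}"

    def _split_time(node: int) -> float:
        a, _ = parents[node]
        return birth[a]

    tree_str = f"({newick(0, 0)},{newick(1, 0)});"
    return RootedTree.from_newick(tree_str)


# ---------------------------------------------------------------------------
# Genome layouts
# ---------------------------------------------------------------------------

@dataclass
class LayoutSet:
    """Per-species layouts plus the genome sequences carrying the planted
    (exact) inverted repeats."""

    layouts: dict[str, GenomeLayout]
    sequences: dict[str, str]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def generate_layouts(config: SyntheticConfig) -> LayoutSet:
    """Quadripartite circular layouts: LSC | IRa | SSC | IRb, genes placed
    in evenly spaced slots within the single-copy regions with a small
    per-species jitter; IRb is an exact reverse-complement copy of IRa."""
    L, R = config.genome_length, config.ir_length
    non_ir = L - 2 * R
    lsc_len = int(round(0.8 * non_ir))
    ssc_len = non_ir - lsc_len
    lsc = (0, lsc_len)
    ir_a = (lsc_len, lsc_len + R)
    ssc = (lsc_len + R, lsc_len + R + ssc_len)
    ir_b = (L - R, L)

    spans = [3 * c for c in config.codons_list()]
    gene_ids = config.gene_ids
    n_lsc = max(1, int(round(config.n_genes * lsc_len / non_ir)))
    n_lsc = min(n_lsc, config.n_genes)
    assignments = [(gene_ids[i], spans[i], "LSC" if i < n_lsc else "SSC")
                   for i in range(config.n_genes)]

    def region_slots(region: tuple[int, int], members):
        start, end = region
        length = end - start
        total_span = sum(s for _, s, _ in members)
        if total_span > length:
            raise ConfigError(
                f"genes do not fit in the {members[0][2]} region: need "
                f"{total_span} nt, region has {length} nt")
        slot = length // max(len(members), 1)
        return [(start + i * slot, slot) for i in range(len(members))]

    lsc_members = [a for a in assignments if a[2] == "LSC"]
    ssc_members = [a for a in assignments if a[2] == "SSC"]
    slots = {}
    for region, members in ((lsc, lsc_members), (ssc, ssc_members)):
        if not members:
            continue
        for (gid, span, _), (slot_start, slot_len) in zip(
                members, region_slots(region, members)):
            if span > slot_len:
                raise ConfigError(
                    f"gene {gid} (span {span}) does not fit its slot "
                    f"({slot_len} nt)")
            slots[gid] = (slot_start, slot_len, span)

    rng = np.random.default_rng(_gene_seed(config.seed, -2) % (2 ** 31))
    layouts: dict[str, GenomeLayout] = {}
    sequences: dict[str, str] = {}
    for sp in config.species_ids:
        genes = {}
        for gid, (slot_start, slot_len, span) in slots.items():
            slack = slot_len - span
            jitter = min(config.position_jitter, slack // 2)
            offset = slack // 2
            if jitter > 0:
                offset += int(rng.integers(-jitter, jitter + 1))
            offset = max(0, min(offset, slack))
            start = slot_start + offset
            strand = "+" if rng.random() < 0.5 else "-"
            genes[gid] = GeneFeature(gene_id=gid, start=start,
                                     end=start + span, strand=strand)
        seq = list(_random_dna(rng, L))
        ira_seq = "".join(seq[ir_a[0]:ir_a[1]])
        seq[ir_b[0]:ir_b[1]] = genome_geometry.revcomp(ira_seq)
        # break reverse-complement pairing just outside the planted
        # borders so greedy extension stops exactly at them
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for outside_a, outside_b in (
                (ir_a[0] - 1, ir_b[1] % L), (ir_a[1], ir_b[0] - 1)):
            if seq[outside_a] == comp[seq[outside_b]]:
                seq[outside_a] = {"A": "C", "C": "A", "G": "T",
                                  "T": "G"}[seq[outside_a]]
        seq = "".join(seq)
        layouts[sp] = GenomeLayout(species=sp, genome_length=L, ir_a=ir_a,
                                   ir_b=ir_b, genes=genes)
        sequences[sp] = seq
    return LayoutSet(layouts=layouts, sequences=sequences)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    config: SyntheticConfig
    tree: RootedTree
    layout_set: LayoutSet
    alignments: dict[str, CodonAlignment]
    covariates: pd.DataFrame       # gene, mrna_abundance, protein_abundance,
    #                                category
    truth: pd.DataFrame            # gene, mu, omega, distance, mrna,
    #                                z_distance, z_log_mrna, epsilon


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_cohort(config: SyntheticConfig, tree: RootedTree,
                    layout_set: LayoutSet) -> Cohort:
    """Simulate per-gene codon alignments, covariates and the truth table.

    Branch lengths for gene g are the species-tree lengths scaled by the
    planted multiplier mu_g; omega_g is drawn uniformly from
    ``omega_range``; per-gene position-specific nucleotide frequencies are
    Dirichlet perturbations of an AT-rich base, so amino-acid composition
    (and hence the tolerance covariate) varies across genes emergently.
    """
    rng = np.random.default_rng(_gene_seed(config.seed, -3) % (2 ** 31))
    gene_ids = config.gene_ids
    codons = config.codons_list()

    dist_table = genome_geometry.average_gene_distance(layout_set.layouts)
    d = dist_table.set_index("gene").loc[gene_ids,
                                         "mean_distance"].to_numpy()
    z_d = _zscore(d)

    rho = config.covariate_correlation
    log_m_std = (rho * z_d
                 + np.sqrt(1 - rho ** 2) * rng.standard_normal(len(gene_ids)))
    log_m = config.mrna_meanlog + config.mrna_sdlog * log_m_std
    mrna = np.exp(log_m)
    z_m = _zscore(np.log(mrna))

    eps = (rng.standard_normal(len(gene_ids)) * config.noise_sd
           if config.noise_sd > 0 else np.zeros(len(gene_ids)))
    log_mu = config.beta_distance * z_d + config.beta_mrna * z_m + eps
    mu = np.exp(log_mu)
    omega = rng.uniform(config.omega_range[0], config.omega_range[1],
                        size=len(gene_ids))

    base = np.asarray(config.freq_base, dtype=float)
    base = base / base.sum()
    categories = np.where(rng.random(len(gene_ids)) < config.energy_fraction,
                          ENERGY, INFO)
    protein = mrna * np.exp(rng.standard_normal(len(gene_ids))
                            * config.protein_noise_sdlog)
    protein = np.where(rng.random(len(gene_ids))
                       < config.protein_missing_fraction, np.nan, protein)

    alignments: dict[str, CodonAlignment] = {}
    for g, gid in enumerate(gene_ids):
        freqs = rng.dirichlet(base * config.freq_concentration, size=3)
        freqs = np.maximum(freqs, 1e-4)
        freqs = freqs / freqs.sum(axis=1, keepdims=True)
        params = codon_model.MG94Params(
            omega=float(omega[g]), exchangeabilities=np.ones(6),
            freqs=freqs)
        # mu_g multiplies the background (synonymous) clock.  Realized
        # branch lengths count all substitutions, so a gene under stronger
        # purifying selection realizes fewer of them per unit clock time:
        # scale by P_S + omega * P_N to keep E[dS] proportional to mu_g.
        p_s = codon_model.build_rate_matrix(
            codon_model.MG94Params(omega=1.0,
                                   exchangeabilities=np.ones(6),
                                   freqs=freqs)).rho_S
        edge_scale = float(mu[g]) * (p_s + float(omega[g]) * (1.0 - p_s))
        scaled = tree.clone()
        for edge in scaled.tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * edge_scale
        alignments[gid] = codon_model.simulate_alignment(
            scaled, params, codons[g], seed=_gene_seed(config.seed, g),
            gene_id=gid)

    covariates = pd.DataFrame({
        "gene": gene_ids,
        "mrna_abundance": mrna,
        "protein_abundance": protein,
        "category": categories,
    })
    truth = pd.DataFrame({
        "gene": gene_ids,
        "mu": mu,
        "omega": omega,
        "distance": d,
        "mrna": mrna,
        "z_distance": z_d,
        "z_log_mrna": z_m,
        "epsilon": eps,
    })
    return Cohort(config=config, tree=tree, layout_set=layout_set,
                  alignments=alignments, covariates=covariates, truth=truth)


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Tree + layouts + simulated alignments in one call."""
    tree = generate_species_tree(config)
    layout_set = generate_layouts(config)
    return simulate_cohort(config, tree, layout_set)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir) -> None:
    """Write the cohort as plain-text files: per-gene FASTA, Newick tree,
    annotation/covariate/truth TSVs and a TOML config echo."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for gid, aln in cohort.alignments.items():
        write_fasta(aln.sequences, out / f"{gid}.fasta")
    write_newick(cohort.tree, out / "tree.nwk")
    write_annotations(cohort.layout_set.layouts, out / "layouts.tsv")
    cohort.covariates.to_csv(out / "covariates.tsv", sep="\t", index=False)
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    dump_toml(cohort.config.as_dict(), out / "config.toml")
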