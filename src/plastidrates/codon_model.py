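"""MG94xREV+F3X4 codon substitution model.

The model acts on the 61 sense codons of the standard genetic code (the
state space shrinks accordingly for other code tables).  A substitution is
allowed only between codons differing at a single nucleotide position; its
rate is

    q_ij = r_ab * f_p(b) * omega^[i->j changes the amino acid]

where ``r_ab`` are the six symmetric (REV) nucleotide exchangeabilities for
the unordered pair {a, b}, ``f_p(b)`` is the equilibrium frequency of the
target nucleotide at codon position p, and ``omega`` is the
nonsynonymous/synonymous rate ratio.  Equilibrium codon frequencies follow
the F3X4 convention, pi_c proportional to f_1(c1) f_2(c2) f_3(c3) over sense
codons, which makes the chain reversible.  The generator is rescaled so
that one unit of branch length equals one expected substitution per
*nucleotide* site (sum_i pi_i |q_ii| = 3 per codon), so total tree lengths
are directly comparable across genes.

Gene-wide synonymous and nonsynonymous rates are obtained by partitioning
every branch length into synonymous and nonsynonymous flux and normalising
each share by the corresponding share of a neutral (omega = 1) chain:

    dS_b = t_b * rho_S(omega) / (3 * P_S)
    dN_b = t_b * rho_N(omega) / (3 * P_N)

with ``rho_S`` the synonymous fraction of total substitution flux at the
fitted omega and ``P_S`` the same fraction at omega = 1 (the synonymous
fraction of sites).  Under a single gene-wide omega this construction
satisfies dN_b/dS_b = omega exactly on every branch.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.optimize import minimize, minimize_scalar

from .alignment_prep import CodonAlignment
from .errors import ConfigError, ConvergenceError, DataError, NumericalError
from .io_formats import RootedTree

__all__ = [
    "MG94Params",
    "CodonRateMatrix",
    "MG94Fit",
    "build_rate_matrix",
    "empirical_f3x4",
    "log_likelihood",
    "fit_gene",
    "simulate_alignment",
    "saturation_report",
    "NUCLEOTIDES",
    "EXCHANGEABILITY_PAIRS",
]

NUCLEOTIDES = "ACGT"
EXCHANGEABILITY_PAIRS = (("A", "C"), ("A", "G"), ("A", "T"),
                         ("C", "G"), ("C", "T"), ("G", "T"))
_PAIR_INDEX = {frozenset(p): k for k, p in enumerate(EXCHANGEABILITY_PAIRS)}

OMEGA_BOUNDS = (1e-4, 10.0)
BRANCH_BOUNDS = (1e-9, 10.0)
RATE_BOUNDS = (1e-3, 100.0)


# ---------------------------------------------------------------------------
# Genetic-code machinery (cached per NCBI table id)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _CodeTables:
    table_id: int
    codons: tuple[str, ...]          # sense codons, lexicographic
    index: dict[str, int]
    amino_acids: tuple[str, ...]
    # single-nucleotide neighbour structure (flattened over ordered pairs)
    src: np.ndarray                  # state index i
    dst: np.ndarray                  # state index j
    pos: np.ndarray                  # codon position 0..2 of the change
    to_nuc: np.ndarray               # target nucleotide index 0..3
    pair: np.ndarray                 # exchangeability pair index 0..5
    nonsyn: np.ndarray               # bool: amino acid changes

    @property
    def n_states(self) -> int:
        return len(self.codons)


@functools.lru_cache(maxsize=None)
def code_tables(table_id: int = 1) -> _CodeTables:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    codons = tuple(sorted(table.forward_table))
    index = {c: i for i, c in enumerate(codons)}
    aas = tuple(table.forward_table[c] for c in codons)
    src, dst, pos, to_nuc, pair, nonsyn = [], [], [], [], [], []
    nuc_index = {n: k for k, n in enumerate(NUCLEOTIDES)}
    for i, ci in enumerate(codons):
        for p in range(3):
            for b in NUCLEOTIDES:
                if b == ci[p]:
                    continue
                cj = ci[:p] + b + ci[p + 1:]
                j = index.get(cj)
                if j is None:       # change to a stop codon: disallowed
                    continue
                src.append(i)
                dst.append(j)
                pos.append(p)
                to_nuc.append(nuc_index[b])
                pair.append(_PAIR_INDEX[frozenset((ci[p], b))])
                nonsyn.append(aas[i] != aas[j])
    return _CodeTables(
        table_id=table_id, codons=codons, index=index, amino_acids=aas,
        src=np.array(src), dst=np.array(dst), pos=np.array(pos),
        to_nuc=np.array(to_nuc), pair=np.array(pair),
        nonsyn=np.array(nonsyn, dtype=bool))


# ---------------------------------------------------------------------------
# Parameters and rate matrix
# ---------------------------------------------------------------------------

@dataclass
class MG94Params:
    """Free parameters of the MG94xREV+F3X4 model.

    ``exchangeabilities`` are ordered (AC, AG, AT, CG, CT, GT); only their
    ratios are identifiable (the generator is renormalised), and fits
    report them scaled to geometric mean 1.  ``freqs`` is the 3x4 matrix of
    position-specific nucleotide frequencies (rows sum to 1, column order
    ACGT).  ``branch_lengths`` (edge id -> t, expected substitutions per
    nucleotide site), when present, override the lengths on the tree passed
    alongside.
    """

    omega: float
    exchangeabilities: np.ndarray
    freqs: np.ndarray
    branch_lengths: dict[str, float] | None = None
    genetic_code: int = 1

    def __post_init__(self):
        self.exchangeabilities = np.asarray(self.exchangeabilities,
                                            dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if not OMEGA_BOUNDS[0] <= self.omega <= OMEGA_BOUNDS[1]:
            raise ConfigError(f"omega {self.omega} outside "
                              f"{OMEGA_BOUNDS}")
        if self.exchangeabilities.shape != (6,):
            raise ConfigError("need 6 exchangeabilities (AC AG AT CG CT GT)")
        if np.any(self.exchangeabilities <= 0):
            raise ConfigError("exchangeabilities must be positive")
        if self.freqs.shape != (3, 4):
            raise ConfigError("freqs must be a 3x4 matrix (positions x ACGT)")
        rowsums = self.freqs.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-6):
            raise ConfigError(f"frequency rows must sum to 1, got {rowsums}")
        self.freqs = self.freqs / rowsums[:, None]

    @classmethod
    def uniform(cls, omega: float = 1.0, genetic_code: int = 1
                ) -> "MG94Params":
        return cls(omega=omega, exchangeabilities=np.ones(6),
                   freqs=np.full((3, 4), 0.25), genetic_code=genetic_code)


@dataclass
class CodonRateMatrix:
    """Reversible generator over sense codons with its stationary law."""

    codons: tuple[str, ...]
    pi: np.ndarray
    Q: np.ndarray
    rho_S: float      # synonymous share of total substitution flux
    rho_N: float

    @property
    def n_states(self) -> int:
        return len(self.codons)


def _f3x4_pi(freqs: np.ndarray, code: _CodeTables) -> np.ndarray:
    nuc_index = {n: k for k, n in enumerate(NUCLEOTIDES)}
    pi = np.array([freqs[0, nuc_index[c[0]]]
                   * freqs[1, nuc_index[c[1]]]
                   * freqs[2, nuc_index[c[2]]] for c in code.codons])
    total = pi.sum()
    if total <= 0:
        raise NumericalError("degenerate F3X4 frequencies: no sense codon "
                             "has positive probability")
    return pi / total


def build_rate_matrix(params: MG94Params) -> CodonRateMatrix:
    """Construct the normalised MG94xREV+F3X4 generator.

    Rows sum to zero, detailed balance holds by construction, and the
    matrix is scaled so sum_i pi_i * (-q_ii) = 3 (one expected substitution
    per nucleotide site per unit branch length).
    """
    code = code_tables(params.genetic_code)
    if np.any(params.freqs <= 0):
        raise NumericalError(
            "degenerate frequency: every nucleotide must have positive "
            "frequency at every codon position (floor empirical zeros)")
    n = code.n_states
    pi = _f3x4_pi(params.freqs, code)
    rates = (params.exchangeabilities[code.pair]
             * params.freqs[code.pos, code.to_nuc])
    rates = np.where(code.nonsyn, rates * params.omega, rates)
    Q = np.zeros((n, n))
    Q[code.src, code.dst] = rates
    flux = pi[code.src] * rates
    total_flux = flux.sum()
    rho_S = flux[~code.nonsyn].sum() / total_flux
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = total_flux / 3.0
    Q /= scale
    return CodonRateMatrix(codons=code.codons, pi=pi, Q=Q,
                           rho_S=rho_S, rho_N=1.0 - rho_S)


def flux_shares(params: MG94Params) -> tuple[float, float, float, float]:
    """(rho_S(omega), rho_N(omega), P_S, P_N): synonymous/nonsynonymous
    flux shares at the fitted omega and at omega = 1 (neutral site
    fractions)."""
    m = build_rate_matrix(params)
    neutral = MG94Params(omega=1.0,
                         exchangeabilities=params.exchangeabilities,
                         freqs=params.freqs,
                         genetic_code=params.genetic_code)
    m1 = build_rate_matrix(neutral)
    return m.rho_S, m.rho_N, m1.rho_S, m1.rho_N


def empirical_f3x4(alignment: CodonAlignment, floor: float = 1e-6
                   ) -> np.ndarray:
    """Position-specific nucleotide frequencies counted from an alignment.

    Codons containing gaps or ambiguity are skipped entirely; zero counts
    are floored at ``floor`` and rows renormalised, so the rate matrix is
    never degenerate.
    """
    counts = np.zeros((3, 4))
    nuc_index = {n: k for k, n in enumerate(NUCLEOTIDES)}
    for seq in alignment.sequences.values():
        s = seq.upper()
        for j in range(0, len(s), 3):
            codon = s[j:j + 3]
            if any(c not in nuc_index for c in codon):
                continue
            for p in range(3):
                counts[p, nuc_index[codon[p]]] += 1
    if counts.sum() == 0:
        raise DataError(f"{alignment.gene_id}: no unambiguous codons for "
                        "frequency estimation")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    freqs = np.maximum(freqs, floor)
    return freqs / freqs.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Tree indexing and the pruning engine
# ---------------------------------------------------------------------------

class TreeIndex:
    """Array view of a rooted tree: nodes in postorder (root last), edge
    lengths stored on the child node."""

    def __init__(self, tree: RootedTree):
        dtree = tree.tree
        nodes = list(dtree.postorder_node_iter())
        self.n_nodes = len(nodes)
        node_id = {id(n): k for k, n in enumerate(nodes)}
        self.root = self.n_nodes - 1
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.lengths = np.zeros(self.n_nodes)
        self.is_leaf = np.zeros(self.n_nodes, dtype=bool)
        self.labels: list[str] = []
        self.leaf_index: dict[str, int] = {}
        self.edge_ids: list[str] = [""] * self.n_nodes
        for k, node in enumerate(nodes):
            if node.parent_node is not None:
                p = node_id[id(node.parent_node)]
                self.parent[k] = p
                self.children[p].append(k)
                self.lengths[k] = (node.edge.length
                                   if node.edge.length is not None else 0.0)
            if node.is_leaf():
                self.is_leaf[k] = True
                label = node.taxon.label
                self.labels.append(label)
                self.leaf_index[label] = k
                self.edge_ids[k] = label
            else:
                self.edge_ids[k] = f"node{k}"
        self.postorder = list(range(self.n_nodes))
        self.preorder = list(reversed(self.postorder))
        self.nonroot = [k for k in self.postorder if k != self.root]


def _encode_alignment(alignment: CodonAlignment, code: _CodeTables,
                      leaf_order: list[str]) -> tuple[np.ndarray, np.ndarray,
                                                      np.ndarray]:
    """Codon-index matrix (taxa x columns, -1 = missing), compressed into
    unique site patterns.  Returns (patterns, weights, first_column)."""
    n_cols = alignment.n_codons
    mat = np.empty((len(leaf_order), n_cols), dtype=np.int16)
    for r, sp in enumerate(leaf_order):
        seq = alignment.sequences[sp].upper()
        for j in range(n_cols):
            mat[r, j] = code.index.get(seq[3 * j:3 * j + 3], -1)
    patterns, first, counts = np.unique(
        mat, axis=1, return_index=True, return_counts=True)
    return patterns, counts.astype(float), first


class _PruningEngine:
    """Felsenstein pruning over compressed site patterns with per-node
    rescaling; also provides outside ('up') partials so single-branch
    likelihood curves are cheap during branch-length optimisation."""

    def __init__(self, alignment: CodonAlignment, tree: RootedTree,
                 genetic_code: int = 1):
        self.code = code_tables(genetic_code)
        self.tindex = TreeIndex(tree)
        aln_species = set(alignment.species)
        tree_species = set(self.tindex.labels)
        if aln_species != tree_species:
            raise DataError(
                "alignment/tree species mismatch; only in alignment: "
                f"{sorted(aln_species - tree_species)}, only in tree: "
                f"{sorted(tree_species - aln_species)}")
        if alignment.n_codons < 1:
            raise DataError("alignment has no columns")
        self.patterns, self.weights, self.first_col = _encode_alignment(
            alignment, self.code, self.tindex.labels)
        n = self.code.n_states
        K = self.patterns.shape[1]
        self.n_states, self.n_patterns = n, K
        self.leaf_partials = np.zeros((len(self.tindex.labels), n, K))
        for r in range(self.patterns.shape[0]):
            for p in range(K):
                s = self.patterns[r, p]
                if s >= 0:
                    self.leaf_partials[r, s, p] = 1.0
                else:
                    self.leaf_partials[r, :, p] = 1.0
        self._leaf_row = {self.tindex.leaf_index[lab]: r
                          for r, lab in enumerate(self.tindex.labels)}

    # -- transition matrices -------------------------------------------------
    @staticmethod
    def eigen(matrix: CodonRateMatrix):
        d = np.sqrt(matrix.pi)
        S = matrix.Q * d[:, None] / d[None, :]
        w, U = np.linalg.eigh((S + S.T) / 2.0)
        left = U / d[:, None]
        right = U.T * d[None, :]
        return w, left, right

    @staticmethod
    def transition_matrix(eig, t: float) -> np.ndarray:
        w, left, right = eig
        P = (left * np.exp(w * t)) @ right
        return np.maximum(P, 0.0)

    def transition_matrices(self, eig, lengths: np.ndarray) -> np.ndarray:
        w, left, right = eig
        n = len(w)
        ew = np.exp(np.multiply.outer(lengths, w))       # (nodes, n)
        tmp = (left[None, :, :] * ew[:, None, :]).reshape(-1, n)
        P = (tmp @ right).reshape(len(lengths), n, n)    # one large gemm
        np.maximum(P, 0.0, out=P)
        return P

    # -- passes --------------------------------------------------------------
    def down_pass(self, P: np.ndarray):
        ti = self.tindex
        n, K = self.n_states, self.n_patterns
        down = np.empty((ti.n_nodes, n, K))
        scale = np.zeros((ti.n_nodes, K))
        # messages along leaf edges can be computed in one batched product
        leaf_ids = np.nonzero(ti.is_leaf)[0]
        rows = np.array([self._leaf_row[v] for v in leaf_ids])
        msg_leaf = P[leaf_ids] @ self.leaf_partials[rows]
        leaf_msg_index = {v: i for i, v in enumerate(leaf_ids)}
        for v in ti.postorder:
            if ti.is_leaf[v]:
                down[v] = self.leaf_partials[self._leaf_row[v]]
                continue
            part = None
            sc = np.zeros(K)
            for c in ti.children[v]:
                if ti.is_leaf[c]:
                    m = msg_leaf[leaf_msg_index[c]]
                else:
                    m = P[c] @ down[c]
                part = m if part is None else part * m
                sc += scale[c]
            mx = part.max(axis=0)
            bad = mx <= 0
            if np.any(bad):
                col = self.first_col[np.argmax(bad)]
                raise NumericalError(
                    f"zero partial likelihood at codon column {col}")
            down[v] = part / mx
            scale[v] = sc + np.log(mx)
        return down, scale

    def up_pass(self, P: np.ndarray, down, dscale, pi: np.ndarray):
        ti = self.tindex
        n, K = self.n_states, self.n_patterns
        up = np.empty((ti.n_nodes, n, K))
        uscale = np.zeros((ti.n_nodes, K))
        for v in ti.preorder:
            if v == ti.root:
                continue
            u = ti.parent[v]
            if u == ti.root:
                base = np.broadcast_to(pi[:, None], (n, K)).copy()
                bsc = np.zeros(K)
            else:
                base = P[u].T @ up[u]
                bsc = uscale[u].copy()
            for s in ti.children[u]:
                if s == v:
                    continue
                base = base * (P[s] @ down[s])
                bsc += dscale[s]
            mx = base.max(axis=0)
            mx = np.where(mx > 0, mx, 1.0)
            up[v] = base / mx
            uscale[v] = bsc + np.log(mx)
        return up, uscale

    def root_loglik(self, down, dscale, pi: np.ndarray) -> float:
        site = pi @ down[self.tindex.root]
        if np.any(site <= 0):
            col = self.first_col[int(np.argmax(site <= 0))]
            raise NumericalError(
                f"non-finite likelihood at codon column {col}")
        return float(self.weights @ (np.log(site)
                                     + dscale[self.tindex.root]))

    def log_likelihood(self, matrix: CodonRateMatrix,
                       lengths: np.ndarray) -> float:
        eig = self.eigen(matrix)
        P = self.transition_matrices(eig, lengths)
        down, dscale = self.down_pass(P)
        return self.root_loglik(down, dscale, matrix.pi)

    def branch_loglik(self, eig, v: int, t: float, up_v, down_v,
                      scale_v: np.ndarray) -> float:
        """Likelihood as a function of one branch length, all else fixed."""
        Pv = self.transition_matrix(eig, t)
        site = np.einsum("sp,sp->p", up_v, Pv @ down_v)
        if np.any(site <= 0):
            return -np.inf
        return float(self.weights @ (np.log(site) + scale_v))

    def branch_coefficients(self, eig, up_v, down_v) -> np.ndarray:
        """Spectral coefficients C (n x K) such that the per-pattern site
        likelihood along one branch is site_p(t) = sum_k exp(w_k t) C_kp,
        making the 1-D branch objective essentially free to evaluate."""
        w, left, right = eig
        return (left.T @ up_v) * (right @ down_v)

    def branch_loglik_from_coeff(self, w: np.ndarray, coeff: np.ndarray,
                                 t: float, scale_v: np.ndarray) -> float:
        site = np.exp(w * t) @ coeff
        if np.any(site <= 0):
            return -np.inf
        return float(self.weights @ (np.log(site) + scale_v))


# ---------------------------------------------------------------------------
# Public likelihood
# ---------------------------------------------------------------------------

def _lengths_from(params: MG94Params, tindex: TreeIndex) -> np.ndarray:
    if params.branch_lengths is None:
        return tindex.lengths.copy()
    lengths = np.zeros(tindex.n_nodes)
    for v in tindex.nonroot:
        eid = tindex.edge_ids[v]
        if eid not in params.branch_lengths:
            raise ConfigError(f"missing branch length for edge {eid!r}")
        lengths[v] = params.branch_lengths[eid]
    return lengths


def log_likelihood(alignment: CodonAlignment, tree: RootedTree,
                   params: MG94Params) -> float:
    """Log-likelihood of a codon alignment on a rooted tree under
    MG94xREV+F3X4 (Felsenstein pruning; gaps/ambiguity integrate over all
    sense codons)."""
    engine = _PruningEngine(alignment, tree, params.genetic_code)
    matrix = build_rate_matrix(params)
    lengths = _lengths_from(params, engine.tindex)
    return engine.log_likelihood(matrix, lengths)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class MG94Fit:
    """Result of a maximum-likelihood gene fit on a fixed topology."""

    gene_id: str
    params: MG94Params
    log_likelihood: float
    branch_table: pd.DataFrame            # edge_id, length, dS, dN
    dS: float
    dN: float
    dn_ds: float
    rho_S: float
    rho_N: float
    P_S: float
    P_N: float
    n_iterations: int
    converged: bool
    tree_length: float = 0.0

    @property
    def omega(self) -> float:
        return self.params.omega

    @property
    def max_branch_dS(self) -> float:
        return float(self.branch_table["dS"].max())

    @property
    def max_branch_dN(self) -> float:
        return float(self.branch_table["dN"].max())


_INIT_BRANCH = 0.05
_INIT_OMEGA = 0.3
_REL_TOL = 1e-8


def _theta_to_params(theta: np.ndarray, freqs: np.ndarray,
                     genetic_code: int) -> MG94Params:
    omega = float(np.clip(np.exp(theta[0]), *OMEGA_BOUNDS))
    r = np.clip(np.exp(theta[1:7]), *RATE_BOUNDS)
    return MG94Params(omega=omega, exchangeabilities=r, freqs=freqs,
                      genetic_code=genetic_code)


def _branch_sweep(engine: _PruningEngine, matrix: CodonRateMatrix,
                  lengths: np.ndarray) -> tuple[np.ndarray, float]:
    """One sweep of per-branch 1-D likelihood maximisation.

    Each branch is optimised against outside/inside partials computed at
    the sweep's starting lengths (a Jacobi-style update); the joint update
    is accepted only if it improves the exact log-likelihood, with step
    halving toward the old lengths as a safeguard, and a sequential
    (Gauss-Seidel) fallback if even damped steps fail.
    """
    ti = engine.tindex
    eig = engine.eigen(matrix)
    P = engine.transition_matrices(eig, lengths)
    down, dscale = engine.down_pass(P)
    up, uscale = engine.up_pass(P, down, dscale, matrix.pi)
    ll0 = engine.root_loglik(down, dscale, matrix.pi)

    w = eig[0]
    proposed = lengths.copy()
    for v in ti.nonroot:
        sc = uscale[v] + dscale[v]
        coeff = engine.branch_coefficients(eig, up[v], down[v])
        res = minimize_scalar(
            lambda t: -engine.branch_loglik_from_coeff(w, coeff, t, sc),
            bounds=BRANCH_BOUNDS, method="bounded",
            options={"xatol": 1e-8})
        proposed[v] = res.x

    step = 1.0
    for _ in range(6):
        cand = lengths + step * (proposed - lengths)
        Pc = engine.transition_matrices(eig, cand)
        dc, dsc = engine.down_pass(Pc)
        ll = engine.root_loglik(dc, dsc, matrix.pi)
        if ll >= ll0:
            return cand, ll
        step /= 2.0

    # sequential fallback: optimise one branch at a time with fresh partials
    cur = lengths.copy()
    ll = ll0
    for v in ti.nonroot:
        Pc = engine.transition_matrices(eig, cur)
        dn, dsn = engine.down_pass(Pc)
        un, usn = engine.up_pass(Pc, dn, dsn, matrix.pi)
        sc = usn[v] + dsn[v]
        coeff = engine.branch_coefficients(eig, un[v], dn[v])
        res = minimize_scalar(
            lambda t: -engine.branch_loglik_from_coeff(w, coeff, t, sc),
            bounds=BRANCH_BOUNDS, method="bounded",
            options={"xatol": 1e-8})
        if -res.fun >= ll:
            cur[v] = res.x
            ll = -res.fun
    return cur, ll


def fit_gene(alignment: CodonAlignment, topology: RootedTree,
             genetic_code: int = 1, max_outer: int = 200) -> MG94Fit:
    """Fit the MG94xREV+F3X4 model to one gene on a fixed topology.

    Position frequencies are fixed at their empirical (F3X4) values; a
    single gene-wide omega, five free exchangeabilities (GT pinned to 1)
    and all branch lengths are estimated by nested coordinate ascent:
    bounded quasi-Newton for (omega, r), per-branch bounded 1-D
    optimisation for lengths.  Starts are fixed (t = 0.05, omega = 0.3,
    r = 1) so refitting the same alignment is bit-reproducible.
    Convergence: relative log-likelihood change < 1e-8 between outer
    iterations.
    """
    if len(alignment.species) < 3:
        raise DataError(f"{alignment.gene_id}: need >= 3 species")
    distinct = {s.upper() for s in alignment.sequences.values()}
    if len(distinct) < 2:
        raise DataError(f"{alignment.gene_id}: all sequences identical; "
                        "zero tree length, nothing to fit")
    freqs = empirical_f3x4(alignment)
    engine = _PruningEngine(alignment, topology, genetic_code)
    ti = engine.tindex

    lengths = np.full(ti.n_nodes, _INIT_BRANCH)
    lengths[ti.root] = 0.0
    # all six exchangeabilities are free: only their ratios matter (the
    # generator is renormalised), and pinning one can create an unbounded
    # ridge when that substitution class is absent from a small alignment
    theta = np.concatenate([[np.log(_INIT_OMEGA)], np.zeros(6)])
    bounds = ([(np.log(OMEGA_BOUNDS[0]), np.log(OMEGA_BOUNDS[1]))]
              + [(np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1]))] * 6)

    def neg_ll(th: np.ndarray) -> float:
        p = _theta_to_params(th, freqs, genetic_code)
        m = build_rate_matrix(p)
        return -engine.log_likelihood(m, lengths)

    ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_outer + 1):
        # a short first rate step (branch lengths are still at their
        # crude starting values), one thorough second step, then small
        # refinements; several cheap branch sweeps per round let the
        # lengths settle between rate updates.  The outer loop guards
        # overall convergence.  If it drags on (e.g. a rate parameter
        # sliding to its boundary), give the inner optimiser a full budget
        # so boundary solutions are reached instead of crawled toward.
        if n_iter <= 5:
            inner_maxiter = {1: 4, 2: 12}.get(n_iter, 3)
        else:
            inner_maxiter = 100
        res = minimize(neg_ll, theta, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-12, "gtol": 1e-8, "eps": 1e-7,
                                "maxiter": inner_maxiter})
        theta = res.x
        params = _theta_to_params(theta, freqs, genetic_code)
        matrix = build_rate_matrix(params)
        for _ in range(4):
            lengths, ll_new = _branch_sweep(engine, matrix, lengths)
        if np.isfinite(ll) and abs(ll_new - ll) <= _REL_TOL * (abs(ll_new)
                                                               + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    params = _theta_to_params(theta, freqs, genetic_code)
    # report exchangeabilities on the geometric-mean-1 scale
    r = params.exchangeabilities
    params.exchangeabilities = r / np.exp(np.mean(np.log(r)))
    params.branch_lengths = {ti.edge_ids[v]: float(lengths[v])
                             for v in ti.nonroot}
    fit = _assemble_fit(alignment.gene_id, params, ll, ti, lengths,
                        n_iter, converged)
    if not converged:
        raise ConvergenceError(
            f"{alignment.gene_id}: no convergence after {max_outer} outer "
            "iterations", best_fit=fit)
    return fit


def _assemble_fit(gene_id: str, params: MG94Params, ll: float,
                  ti: TreeIndex, lengths: np.ndarray, n_iter: int,
                  converged: bool) -> MG94Fit:
    rho_S, rho_N, P_S, P_N = flux_shares(params)
    rows = []
    for v in ti.nonroot:
        t = float(lengths[v])
        rows.append((ti.edge_ids[v], t,
                     t * rho_S / (3.0 * P_S),
                     t * rho_N / (3.0 * P_N)))
    table = pd.DataFrame(rows, columns=["edge_id", "length", "dS", "dN"])
    dS = float(table["dS"].sum())
    dN = float(table["dN"].sum())
    return MG94Fit(
        gene_id=gene_id, params=params, log_likelihood=ll,
        branch_table=table, dS=dS, dN=dN,
        dn_ds=dN / dS if dS > 0 else float("nan"),
        rho_S=rho_S, rho_N=rho_N, P_S=P_S, P_N=P_N,
        n_iterations=n_iter, converged=converged,
        tree_length=float(lengths.sum()))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_alignment(tree: RootedTree, params: MG94Params, n_codons: int,
                       seed: int, gene_id: str = "gene") -> CodonAlignment:
    """Simulate an indel-free codon alignment on a rooted tree.

    Root codons are drawn from the stationary law pi; each child state is
    sampled from exp(Q t) given its parent.  Deterministic given seed.
    """
    if n_codons < 1:
        raise ConfigError("n_codons must be >= 1")
    matrix = build_rate_matrix(params)
    code = code_tables(params.genetic_code)
    ti = TreeIndex(tree)
    lengths = _lengths_from(params, ti)
    eig = _PruningEngine.eigen(matrix)
    rng = np.random.default_rng(seed)
    n = code.n_states

    states = np.empty((ti.n_nodes, n_codons), dtype=np.int64)
    states[ti.root] = rng.choice(n, size=n_codons, p=matrix.pi)
    for v in ti.preorder:
        if v == ti.root:
            continue
        P = _PruningEngine.transition_matrix(eig, lengths[v])
        P = P / P.sum(axis=1, keepdims=True)
        parent_states = states[ti.parent[v]]
        child = np.empty(n_codons, dtype=np.int64)
        for s in np.unique(parent_states):
            idx = np.nonzero(parent_states == s)[0]
            child[idx] = rng.choice(n, size=idx.size, p=P[s])
        states[v] = child

    codon_arr = np.array(code.codons)
    sequences = {}
    for label, v in sorted(ti.leaf_index.items()):
        sequences[label] = "".join(codon_arr[states[v]])
    return CodonAlignment(gene_id=gene_id, sequences=sequences,
                          genetic_code=params.genetic_code)


# ---------------------------------------------------------------------------
# Saturation reporting
# ---------------------------------------------------------------------------

def saturation_report(fits: list[MG94Fit]) -> pd.DataFrame:
    """Per-gene maxima of per-branch dS and dN, used to verify that no
    branch approaches substitutional saturation.  The overall maxima are
    attached as ``df.attrs['max_dS']`` / ``df.attrs['max_dN']``."""
    if not fits:
        raise DataError("no fits supplied")
    rows = [(f.gene_id, f.max_branch_dS, f.max_branch_dN) for f in fits]
    df = pd.DataFrame(rows, columns=["gene", "max_branch_dS",
                                     "max_branch_dN"])
    df.attrs["max_dS"] = float(df["max_branch_dS"].max())
    df.attrs["max_dN"] = float(df["max_branch_dN"].max())
    return df
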