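"""Independent brute-force oracles used by the test suite.

Each oracle computes its quantity by direct enumeration or dense linear
algebra, sharing no code path with the implementation it checks.
"""

import itertools

import numpy as np
import pandas as pd
from scipy.linalg import expm

from plastidrates.codon_model import build_rate_matrix, code_tables
from plastidrates.io_formats import GenomeLayout


def brute_force_loglik(alignment, node_spec, params):
    """Dense-matrix likelihood: explicit matrix exponentials and summation
    over all internal-node states.  ``node_spec`` is a nested tuple
    ``((child, child, ...), t)`` with leaves as ``(name, t)``."""
    m = build_rate_matrix(params)
    code = code_tables(params.genetic_code)
    idx = code.index
    n = len(code.codons)

    def partial(spec, col):
        if isinstance(spec[0], str):          # leaf
            name = spec[0]
            codon = alignment.sequences[name][3 * col:3 * col + 3].upper()
            vec = np.zeros(n)
            if codon in idx:
                vec[idx[codon]] = 1.0
            else:
                vec[:] = 1.0
            return vec
        vec = np.ones(n)
        for child in spec[0]:
            P = expm(m.Q * child[1])
            vec = vec * (P @ partial(child, col))
        return vec

    return sum(float(np.log(m.pi @ partial(node_spec, col)))
               for col in range(alignment.n_codons))


def brute_force_distance(layout: GenomeLayout, gene_id: str) -> int:
    """Walk the circle outward from the gene midpoint one nucleotide at a
    time until an IR boundary coordinate is hit."""
    L = layout.genome_length
    mid = layout.midpoint(gene_id)
    borders = {layout.ir_a[0] % L, layout.ir_a[1] % L,
               layout.ir_b[0] % L, layout.ir_b[1] % L}
    for step in range(L):
        if (mid + step) % L in borders or (mid - step) % L in borders:
            return step
    raise AssertionError("no border found")


def lmg_all_orderings(y, X: pd.DataFrame) -> dict[str, float]:
    """Literal LMG: refit every predictor ordering and average the
    sequential R^2 increments."""
    names = list(X.columns)
    y = np.asarray(y, dtype=float)
    arr = X.to_numpy(dtype=float)
    tss = ((y - y.mean()) ** 2).sum()

    def r2(cols):
        if not cols:
            return 0.0
        d = np.column_stack([np.ones(len(y))] + [arr[:, c] for c in cols])
        beta, *_ = np.linalg.lstsq(d, y, rcond=None)
        return 1 - ((y - d @ beta) ** 2).sum() / tss

    shares = dict.fromkeys(names, 0.0)
    orders = list(itertools.permutations(range(len(names))))
    for order in orders:
        used = []
        for k in order:
            before = r2(tuple(sorted(used)))
            used.append(k)
            after = r2(tuple(sorted(used)))
            shares[names[k]] += after - before
    return {k: v / len(orders) for k, v in shares.items()}


def rank_sum_exact_p(a, b) -> float:
    """Exact two-sided rank-sum p-value by enumerating all group
    assignments of the pooled ranks (no ties assumed)."""
    pooled = np.array(list(a) + list(b), dtype=float)
    ranks = pooled.argsort().argsort() + 1
    observed = ranks[:len(a)].sum()
    null = np.array([sum(c) for c in
                     itertools.combinations(ranks, len(a))])
    mean = null.mean()
    extreme = np.sum(np.abs(null - mean) >= abs(observed - mean) - 1e-9)
    return float(extreme / len(null))
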