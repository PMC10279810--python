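"""Shared fixtures: small trees, parameter sets and a miniature synthetic
cohort (session-scoped, so the expensive pieces are built once)."""

import numpy as np
import pytest

from plastidrates.codon_model import MG94Params, simulate_alignment
from plastidrates.io_formats import RootedTree
from plastidrates.synthetic_data import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def three_taxon_tree() -> RootedTree:
    return RootedTree.from_newick("((A:0.1,B:0.2):0.05,C:0.3);")


@pytest.fixture(scope="session")
def skewed_params() -> MG94Params:
    rng = np.random.default_rng(1)
    return MG94Params(
        omega=0.4,
        exchangeabilities=np.array([1.2, 2.5, 0.8, 1.1, 3.0, 1.0]),
        freqs=rng.dirichlet(np.ones(4) * 20, size=3))


@pytest.fixture(scope="session")
def tiny_alignment(three_taxon_tree, skewed_params):
    return simulate_alignment(three_taxon_tree, skewed_params, 5, seed=3)


@pytest.fixture(scope="session")
def mini_config() -> SyntheticConfig:
    # small enough for fast unit tests, big enough to exercise geometry
    return SyntheticConfig(n_species=6, n_genes=5, codons_per_gene=30,
                           genome_length=40_000, ir_length=6_000,
                           position_jitter=200, seed=101)


@pytest.fixture(scope="session")
def mini_cohort(mini_config):
    return generate_cohort(mini_config)
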