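import numpy as np
import pytest
from scipy.stats import chisquare

from plastidrates.alignment_prep import CodonAlignment
from plastidrates.codon_model import (MG94Params, build_rate_matrix,
                                      code_tables, empirical_f3x4, fit_gene,
                                      log_likelihood, saturation_report,
                                      simulate_alignment)
from plastidrates.errors import ConfigError, DataError
from plastidrates.io_formats import RootedTree


from oracles import brute_force_loglik


class TestRateMatrix:
    def test_uniform_symmetry(self):
        m = build_rate_matrix(MG94Params.uniform(omega=1.0))
        off = m.Q[m.Q > 0]
        assert np.allclose(off, off[0])

    def test_generator_invariants(self, skewed_params):
        m = build_rate_matrix(skewed_params)
        assert np.abs(m.Q.sum(axis=1)).max() < 1e-12
        assert -(m.pi * np.diag(m.Q)).sum() == pytest.approx(3.0, abs=1e-12)

    def test_detailed_balance(self, skewed_params):
        m = build_rate_matrix(skewed_params)
        flux = m.pi[:, None] * m.Q
        assert np.abs(flux - flux.T).max() < 1e-10

    def test_flux_shares_partition(self, skewed_params):
        m = build_rate_matrix(skewed_params)
        assert m.rho_S + m.rho_N == pytest.approx(1.0, abs=1e-12)


class TestLikelihood:
    def test_matches_dense_oracle_three_taxa(self, three_taxon_tree,
                                             skewed_params,
                                             tiny_alignment):
        ll = log_likelihood(tiny_alignment, three_taxon_tree, skewed_params)
        spec = ((( (("A", 0.1), ("B", 0.2)), 0.05), ("C", 0.3)), 0.0)
        oracle = brute_force_loglik(tiny_alignment, spec, skewed_params)
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_matches_dense_oracle_two_taxa(self, skewed_params):
        tree = RootedTree.from_newick("(A:0.07,B:0.21);")
        aln = simulate_alignment(tree, skewed_params, 4, seed=9)
        ll = log_likelihood(aln, tree, skewed_params)
        oracle = brute_force_loglik(
            aln, ((("A", 0.07), ("B", 0.21)), 0.0), skewed_params)
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_zero_length_limit(self, skewed_params):
        tree = RootedTree.from_newick("(A:0.0,B:0.0);")
        m = build_rate_matrix(skewed_params)
        codon = code_tables(1).codons[17]
        aln = CodonAlignment(gene_id="g",
                             sequences={"A": codon * 3, "B": codon * 3})
        ll = log_likelihood(aln, tree, skewed_params)
        assert ll == pytest.approx(3 * np.log(m.pi[17]), abs=1e-9)

    def test_column_duplication_doubles(self, three_taxon_tree,
                                        skewed_params, tiny_alignment):
        doubled = CodonAlignment(
            gene_id="g2",
            sequences={sp: s + s
                       for sp, s in tiny_alignment.sequences.items()})
        ll1 = log_likelihood(tiny_alignment, three_taxon_tree,
                             skewed_params)
        ll2 = log_likelihood(doubled, three_taxon_tree, skewed_params)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_column_permutation_invariant(self, three_taxon_tree,
                                          skewed_params):
        aln = simulate_alignment(three_taxon_tree, skewed_params, 30,
                                 seed=2)
        perm = np.random.default_rng(0).permutation(30)
        shuffled = CodonAlignment(
            gene_id="p",
            sequences={sp: "".join(s[3 * j:3 * j + 3] for j in perm)
                       for sp, s in aln.sequences.items()})
        assert log_likelihood(shuffled, three_taxon_tree, skewed_params) \
            == pytest.approx(
                log_likelihood(aln, three_taxon_tree, skewed_params),
                rel=1e-12)

    def test_species_mismatch_rejected(self, three_taxon_tree,
                                       skewed_params):
        aln = CodonAlignment(gene_id="g",
                             sequences={"A": "AAA", "X": "AAA"})
        with pytest.raises(DataError, match="mismatch"):
            log_likelihood(aln, three_taxon_tree, skewed_params)


class TestSimulation:
    def test_zero_lengths_give_identical_sequences(self, skewed_params):
        tree = RootedTree.from_newick("((A:0.0,B:0.0):0.0,C:0.0);")
        aln = simulate_alignment(tree, skewed_params, 50, seed=4)
        seqs = list(aln.sequences.values())
        assert seqs[0] == seqs[1] == seqs[2]

    def test_seed_determinism(self, three_taxon_tree, skewed_params):
        a = simulate_alignment(three_taxon_tree, skewed_params, 40, seed=6)
        b = simulate_alignment(three_taxon_tree, skewed_params, 40, seed=6)
        c = simulate_alignment(three_taxon_tree, skewed_params, 40, seed=7)
        assert a.sequences == b.sequences
        assert a.sequences != c.sequences

    def test_long_branch_reaches_stationarity(self, skewed_params):
        tree = RootedTree.from_newick("(A:50.0,B:50.0);")
        m = build_rate_matrix(skewed_params)
        aln = simulate_alignment(tree, skewed_params, 10_000, seed=8)
        code = code_tables(1)
        counts = np.zeros(len(code.codons))
        seq = aln.sequences["A"]
        for j in range(10_000):
            counts[code.index[seq[3 * j:3 * j + 3]]] += 1
        # merge rare codons to keep expected counts reasonable
        expected = m.pi * 10_000
        keep = expected >= 5
        obs, exp = counts[keep], expected[keep]
        if (~keep).any():
            obs = np.append(obs, counts[~keep].sum())
            exp = np.append(exp, expected[~keep].sum())
        res = chisquare(obs, exp * obs.sum() / exp.sum())
        assert res.pvalue > 0.01

    def test_invalid_codon_count_rejected(self, three_taxon_tree,
                                          skewed_params):
        with pytest.raises(ConfigError):
            simulate_alignment(three_taxon_tree, skewed_params, 0, seed=1)


class TestFit:
    @pytest.fixture(scope="class")
    def six_taxon_fit(self):
        tree = RootedTree.from_newick(
            "(((A:0.05,B:0.08):0.03,(C:0.06,D:0.04):0.02):0.02,"
            "(E:0.07,F:0.05):0.03);")
        params = MG94Params(omega=0.25,
                            exchangeabilities=np.array(
                                [1.0, 2.0, 0.7, 1.1, 2.4, 0.9]),
                            freqs=np.array([[0.3, 0.2, 0.2, 0.3]] * 3))
        aln = simulate_alignment(tree, params, 200, seed=13)
        return aln, tree, fit_gene(aln, tree)

    def test_dn_ds_equals_omega_identity(self, six_taxon_fit):
        _, _, fit = six_taxon_fit
        assert fit.dn_ds == pytest.approx(fit.omega, abs=1e-9)
        ratio = fit.branch_table["dN"] / fit.branch_table["dS"]
        assert np.abs(ratio - fit.omega).max() < 1e-9

    def test_site_fraction_partitions(self, six_taxon_fit):
        _, _, fit = six_taxon_fit
        assert fit.rho_S + fit.rho_N == pytest.approx(1.0, abs=1e-12)
        assert fit.P_S + fit.P_N == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_refit(self, six_taxon_fit):
        aln, tree, fit = six_taxon_fit
        again = fit_gene(aln, tree)
        assert again.log_likelihood == fit.log_likelihood
        assert again.omega == fit.omega
        assert np.array_equal(
            again.branch_table["length"].to_numpy(),
            fit.branch_table["length"].to_numpy())

    def test_fitted_ll_beats_truth(self, six_taxon_fit):
        aln, tree, fit = six_taxon_fit
        truth = MG94Params(omega=0.25,
                           exchangeabilities=np.array(
                               [1.0, 2.0, 0.7, 1.1, 2.4, 0.9]),
                           freqs=empirical_f3x4(aln))
        assert fit.log_likelihood >= log_likelihood(aln, tree, truth) - 1e-6

    def test_omega_recovery_band(self):
        # band frozen after pilot runs at this seed/size
        from plastidrates.synthetic_data import (SyntheticConfig,
                                                 generate_species_tree)
        cfg = SyntheticConfig(seed=31, tree_height=0.2)
        tree = generate_species_tree(cfg)
        params = MG94Params(omega=0.2,
                            exchangeabilities=np.ones(6),
                            freqs=np.array([[0.3, 0.2, 0.2, 0.3]] * 3))
        aln = simulate_alignment(tree, params, 500, seed=77)
        fit = fit_gene(aln, tree)
        assert 0.15 <= fit.omega <= 0.25

    def test_identical_sequences_rejected(self, three_taxon_tree):
        aln = CodonAlignment(gene_id="g", sequences={
            "A": "ATGAAA", "B": "ATGAAA", "C": "ATGAAA"})
        with pytest.raises(DataError, match="identical"):
            fit_gene(aln, three_taxon_tree)

    def test_too_few_species_rejected(self, three_taxon_tree):
        aln = CodonAlignment(gene_id="g",
                             sequences={"A": "ATGAAA", "B": "ATGCCC"})
        with pytest.raises(DataError, match="3 species"):
            fit_gene(aln, three_taxon_tree)


class TestSaturationReport:
    def test_maxima(self, six_taxon_fits=None):
        tree = RootedTree.from_newick("((A:0.1,B:0.1):0.05,C:0.1);")
        params = MG94Params.uniform(omega=0.5)
        fits = []
        for seed in (1, 2):
            aln = simulate_alignment(tree, params, 60, seed=seed)
            fits.append(fit_gene(aln, tree))
        df = saturation_report(fits)
        assert len(df) == 2
        for fit, row in zip(fits, df.itertuples()):
            assert row.max_branch_dS == pytest.approx(
                fit.branch_table["dS"].max())
        assert df.attrs["max_dS"] == df["max_branch_dS"].max()

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            saturation_report([])
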