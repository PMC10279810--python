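import numpy as np
import pytest

from plastidrates.errors import ConfigError
from plastidrates.genome_geometry import revcomp
from plastidrates.synthetic_data import (SyntheticConfig, generate_cohort,
                                         generate_layouts,
                                         generate_species_tree,
                                         write_cohort)


class TestConfigValidation:
    def test_too_few_species(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(n_species=2)

    def test_too_short_genes(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(codons_per_gene=5)

    def test_quadripartite_required(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(ir_length=0)

    def test_geometry_must_fit(self):
        with pytest.raises(ConfigError, match="does not fit"):
            SyntheticConfig(n_genes=40, codons_per_gene=300,
                            genome_length=40_000, ir_length=10_000)

    def test_omega_range_in_unit_interval(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(omega_range=(0.5, 1.5))


class TestSpeciesTree:
    def test_three_species_edge_count(self):
        cfg = SyntheticConfig(n_species=3, n_genes=1,
                              genome_length=20_000, ir_length=3_000)
        tree = generate_species_tree(cfg)
        assert tree.n_leaves == 3
        assert tree.n_edges == 4

    def test_determinism(self, mini_config):
        t1 = generate_species_tree(mini_config)
        t2 = generate_species_tree(mini_config)
        assert t1.to_newick() == t2.to_newick()

    def test_seed_changes_tree(self):
        a = generate_species_tree(SyntheticConfig(seed=1))
        b = generate_species_tree(SyntheticConfig(seed=2))
        assert a.to_newick() != b.to_newick()

    def test_height_scaled(self, mini_config):
        tree = generate_species_tree(mini_config)
        depths = tree.tree.calc_node_root_distances(
            return_leaf_distances_only=True)
        assert max(depths) == pytest.approx(mini_config.tree_height,
                                            rel=1e-9)


class TestLayouts:
    def test_ir_is_reverse_complement_copy(self, mini_cohort):
        ls = mini_cohort.layout_set
        for sp, layout in ls.layouts.items():
            seq = ls.sequences[sp]
            a = seq[layout.ir_a[0]:layout.ir_a[1]]
            b = seq[layout.ir_b[0]:layout.ir_b[1]]
            assert b == revcomp(a)
            assert len(a) == mini_cohort.config.ir_length

    def test_genes_do_not_overlap(self, mini_cohort):
        for layout in mini_cohort.layout_set.layouts.values():
            spans = sorted((g.start, g.end)
                           for g in layout.genes.values())
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_layout_determinism(self, mini_config):
        a = generate_layouts(mini_config)
        b = generate_layouts(mini_config)
        assert a.sequences == b.sequences


class TestCohort:
    def test_truth_equation_recomputable(self, mini_cohort):
        tr = mini_cohort.truth
        cfg = mini_cohort.config
        log_mu = (cfg.beta_distance * tr["z_distance"]
                  + cfg.beta_mrna * tr["z_log_mrna"] + tr["epsilon"])
        assert np.allclose(np.log(tr["mu"]), log_mu, atol=1e-12)

    def test_no_effects_no_noise_gives_unit_multipliers(self):
        cfg = SyntheticConfig(n_species=4, n_genes=4, codons_per_gene=20,
                              genome_length=30_000, ir_length=4_000,
                              beta_distance=0.0, beta_mrna=0.0,
                              noise_sd=0.0, seed=5)
        cohort = generate_cohort(cfg)
        assert np.allclose(cohort.truth["mu"], 1.0)

    def test_bit_identical_reruns(self, mini_config, mini_cohort,
                                  tmp_path):
        again = generate_cohort(mini_config)
        for gid in mini_cohort.alignments:
            assert again.alignments[gid].sequences == \
                mini_cohort.alignments[gid].sequences
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort(mini_cohort, d1)
        write_cohort(again, d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_omega_within_range(self, mini_cohort):
        lo, hi = mini_cohort.config.omega_range
        assert ((mini_cohort.truth["omega"] >= lo)
                & (mini_cohort.truth["omega"] <= hi)).all()

    def test_alignments_are_indel_free_and_complete(self, mini_cohort):
        cfg = mini_cohort.config
        for gid, aln in mini_cohort.alignments.items():
            assert sorted(aln.species) == sorted(cfg.species_ids)
            assert aln.n_codons == cfg.codons_per_gene
            assert all("-" not in s for s in aln.sequences.values())

    def test_covariate_correlation_knob(self):
        base = dict(n_species=4, n_genes=30, codons_per_gene=10,
                    genome_length=120_000, ir_length=10_000, seed=9)
        rho0 = generate_cohort(SyntheticConfig(**base))
        rho9 = generate_cohort(SyntheticConfig(
            **base, covariate_correlation=0.9))
        r0 = np.corrcoef(rho0.truth["z_distance"],
                         rho0.truth["z_log_mrna"])[0, 1]
        r9 = np.corrcoef(rho9.truth["z_distance"],
                         rho9.truth["z_log_mrna"])[0, 1]
        assert abs(r0) < 0.5
        assert r9 > 0.7

    def test_mrna_negative_effect_visible_in_truth(self):
        cfg = SyntheticConfig(n_species=4, n_genes=40, codons_per_gene=10,
                              genome_length=150_000, ir_length=10_000,
                              beta_distance=0.0, beta_mrna=-0.5,
                              noise_sd=0.0, seed=3)
        cohort = generate_cohort(cfg)
        r = np.corrcoef(np.log(cohort.truth["mrna"]),
                        np.log(cohort.truth["mu"]))[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-9)
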