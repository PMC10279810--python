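# plastidrates

**What constrains the rate of plastid gene evolution?**

Angiosperm chloroplast (plastid) genomes evolve slowly and keep a highly
conserved quadripartite layout: two single-copy regions separated by two
large inverted repeats (IRs) that likely host the replication origins.
Yet the protein-coding genes inside them differ many-fold in how fast they
evolve.  `plastidrates` is a reusable pipeline for dissecting that
variation.  It is aimed at molecular-evolution researchers who have
per-gene codon alignments, a species topology and genome annotations, and
want to know how much of the between-gene rate variation is explained by
gene position, sequence composition and expression.

The pipeline:

1. **estimates rates** — for each gene, maximum-likelihood fits of the
   MG94×REV+F3X4 codon substitution model on a fixed rooted topology:
   q_ij = r_ab · f_p(b) · ω^[nonsyn] over the 61 sense codons, with
   gene-wide dS and dN obtained as the total tree length on the
   synonymous and nonsynonymous scale (dS_b = t_b·ρ_S(ω)/(3P_S),
   dN_b = t_b·ρ_N(ω)/(3P_N); dN_b/dS_b ≡ ω);
2. **computes covariates** — distance of each gene's midpoint to the
   closest inverted-repeat border (IRs detected directly from the genome
   sequence), a BLOSUM62 substitution-tolerance score
   (T_a = geometric mean of the odds ratios 2^(s_ab/2) to the 19 other
   residues, averaged over the concatenated protein), GC3/GC12, and
   mRNA/protein abundance;
3. **decomposes variance** — Welch/Wilcoxon group contrasts, fold
   differences, simple OLS regressions, all-subsets model search
   (adjusted R² criterion) and LMG relative importance (the average
   sequential R² contribution of each predictor over all orderings).

A first-class synthetic-data module generates whole cohorts — Yule
species tree, quadripartite genomes with exact planted IRs, log-normal
mRNA abundances, and codon alignments simulated with planted covariate
effects (log μ_g = β_dist·z(d_g) + β_mRNA·z(log m_g) + ε_g) — so every
stage is testable against known truth.

## Worked example

```python
import numpy as np
from plastidrates.synthetic_data import SyntheticConfig, generate_cohort
from plastidrates.codon_model import fit_gene
from plastidrates.constraint_stats import simple_regression

cfg = SyntheticConfig(n_genes=10, codons_per_gene=80, seed=7)
cohort = generate_cohort(cfg)               # tree, genomes, alignments
fits = {g: fit_gene(a, cohort.tree) for g, a in cohort.alignments.items()}

f = fits["gene01"]
print(f"gene01: dS={f.dS:.3f} dN={f.dN:.3f} dN/dS={f.dn_ds:.3f}")

ds = [fits[g].dS for g in cohort.truth["gene"]]
r = simple_regression(ds, cohort.truth["distance"])
print(f"dS ~ distance: slope={r.slope:.2e} R2={r.r_squared:.2f} "
      f"p={r.p_value:.3f}")
r = simple_regression(ds, np.log10(cohort.truth["mrna"]))
print(f"dS ~ log10 mRNA: slope={r.slope:.3f} R2={r.r_squared:.2f} "
      f"p={r.p_value:.3f}")
```

Output:

```
gene01: dS=1.041 dN=0.250 dN/dS=0.240
dS ~ distance: slope=-1.53e-05 R2=0.44 p=0.035
dS ~ log10 mRNA: slope=-0.462 R2=0.54 p=0.016
```

Both planted effects are negative, and the fitted regressions recover
that: genes further from the inverted repeat and genes with higher mRNA
abundance have lower synonymous rates.  The slope on distance is per
nucleotide of genomic distance, hence its small magnitude.

The same analysis runs end-to-end from a single TOML config:

```bash
plastidrates run-all --config run.toml --seed 7
```

which writes `gene_covariates.tsv` (one row per gene joining dS, dN,
dN/dS with distance, tolerance, GC3 and expression), contrast/regression/
all-subsets/relative-importance tables, a saturation report of per-branch
maxima, and a manifest with the config hash for reproducibility.

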