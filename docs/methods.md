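# Methods

## Scientific setting

Angiosperm plastid genomes are small, slowly evolving, circular molecules
with a conserved quadripartite architecture: a large and a small
single-copy region separated by two large inverted repeats (IRs), the
likely neighbourhood of the replication origins.  The package asks what
constrains the rate of molecular evolution of the single-copy
protein-coding genes: their position relative to the IR, the amino-acid
composition of their products, their nucleotide composition (GC3), and
their expression level.  It does so by (i) estimating per-gene synonymous
(dS) and nonsynonymous (dN) substitution rates under a codon model on a
fixed species topology, (ii) computing the covariates, and (iii)
decomposing the variance of the rates across covariates.

## Codon model

Rates are estimated under MG94xREV+F3X4 on the 61 sense codons of the
standard genetic code.  Substitutions are single-nucleotide only:

    q_ij = r_ab * f_p(b) * omega^[nonsynonymous]

with six symmetric nucleotide exchangeabilities `r_ab` (REV), target
frequencies `f_p(b)` specific to the codon position p of the change, and a
single gene-wide omega.  Stationary codon frequencies follow F3X4
(pi_c proportional to f1(c1) f2(c2) f3(c3) over sense codons), which makes
the chain reversible; detailed balance is exact by construction.  The
generator is rescaled so that one unit of branch length is one expected
substitution per nucleotide site (sum_i pi_i |q_ii| = 3 per codon), making
total tree lengths comparable across genes.  The GY-style parametrisation
with full-codon target frequencies is deliberately not used.

Position frequencies are fixed at their empirical counts (+F3X4 practice);
zero counts are floored at 1e-6 and rows renormalised so the generator is
never degenerate.

### Likelihood and optimisation

The likelihood is computed by Felsenstein pruning over unique codon-column
patterns, with per-node rescaling of partial likelihoods (accumulated log
factors) against underflow.  Transition matrices come from the symmetric
eigendecomposition of the reversible generator; tiny negative round-off
entries are clipped at zero.  Gap or ambiguous codons integrate over all
sense codons.

Fitting holds the topology fixed and maximises over omega, the six
exchangeabilities and all branch lengths by nested coordinate ascent:

* **Rates** (log omega, log r): bounded L-BFGS-B.  All six
  exchangeabilities are free — only their ratios are identifiable because
  the generator is renormalised, so the flat joint-scaling direction is
  harmless, whereas pinning one rate to 1 creates an unbounded ridge
  whenever that substitution class happens to be absent from a small
  alignment.  Reported exchangeabilities are scaled to geometric mean 1.
* **Branch lengths**: per-branch bounded 1-D optimisation against cached
  inside ("down") and outside ("up") partials.  In the eigenbasis the
  single-branch site likelihood is a finite exponential sum
  site_p(t) = sum_k e^{w_k t} C_kp with C precomputable per branch, so
  each 1-D objective evaluation is essentially free.  Branches are
  proposed Jacobi-style from the partials at the sweep start; the joint
  update is accepted only if the exact log-likelihood improves, with step
  halving and a sequential Gauss-Seidel fallback.
* **Schedule**: a short first rate step (4 quasi-Newton iterations, since
  branch lengths are still at their crude start), a thorough second step
  (12), then small refinements (3), with four branch sweeps per round;
  if the outer loop has not converged after five rounds the inner
  optimiser gets a full budget (100) so boundary solutions are reached
  rather than crawled toward.  Starts are fixed (t = 0.05, omega = 0.3,
  r = 1), bounds are t in [1e-9, 10], omega in [1e-4, 10],
  r in [1e-3, 100], and convergence is a relative log-likelihood change
  below 1e-8 between outer rounds, so refits are bit-reproducible.
  Exceeding 200 outer rounds raises a convergence error carrying the best
  fit so far.

### dS/dN partitioning

Each branch length is split into synonymous and nonsynonymous parts via
flux shares: with rho_S(omega) the synonymous fraction of total
substitution flux at the fitted omega, and P_S the same fraction at
omega = 1 (the synonymous site fraction),

    dS_b = t_b rho_S(omega) / (3 P_S),   dN_b = t_b rho_N(omega) / (3 P_N).

Gene-wide dS and dN are the sums over branches ("total tree length" on
each scale), and dN_b/dS_b = omega holds exactly on every branch under a
single gene-wide omega — used as a machine-precision invariant in the
tests.  A single omega is fitted per gene; with one omega, the ratio of
totals and the mean of per-branch ratios coincide, so the distinction
between the two possible definitions of a gene-wide dN/dS is moot.
Saturation is monitored by reporting per-gene maxima of per-branch dS and
dN.

## Covariates

* **Substitution tolerance.**  BLOSUM62 half-bit log-odds scores s_ab are
  back-calculated to odds ratios o_ab = 2^(s_ab/2); the half-bit
  convention matches the matrix's published construction.  Each residue
  gets T_a = geometric mean of its odds to the 19 other standard
  residues (diagonal excluded); a gene's score is the arithmetic mean of
  T over the concatenation of all species' protein sequences, with gaps
  and ambiguity codes excluded from numerator and denominator (a gap
  carries no residue identity).  The 20x20 integer matrix ships as a
  text fixture in NCBI matrix format; B/Z/X and stop columns are
  excluded.
* **GC3 / GC12.**  GC3 is the G+C fraction at third codon positions,
  excluding ATG and TGG (Met and Trp are encoded by single codons, so
  their third position is not free), and excluding gap, stop and
  ambiguous codons.  GC12 is the analogous fraction over positions 1-2
  without the Met/Trp exclusion.  The gene value is the unweighted mean
  across species rather than a pooled count.
* **Gene position.**  Inverted repeats are detected by anchoring k-mers
  (k = 21) of the genome against its reverse complement and greedily
  extending each anchor on the circle; exact matching is the default and
  a mismatch-fraction budget is a parameter.  Tie-break: longest pair,
  then smallest start coordinate.  The detector returns a not-found
  result (not an error) when nothing qualifies.  A gene's position
  covariate is the circular-arc distance from its midpoint to the nearer
  border of the single-copy region containing it, averaged across
  species.  Coordinates are 0-based half-open on the circle; the
  midpoint convention is floor((start + end)/2) with the end unwrapped,
  and the "closest border" is constrained to the gene's own single-copy
  region (a distance is never measured across an IR into the other
  region).
* **Expression.**  mRNA and (optionally) protein abundances are external
  covariates in arbitrary units; mRNA is log10-transformed before
  regression by default (the scale is a config switch recorded in every
  output).

## Statistics

Group contrasts use Welch's unequal-variance t-test for dS and two-sided
Wilcoxon rank-sum tests for dN and dN/dS (configurable); fold differences
are ratios of group means (Welch) or medians (Wilcoxon), and gene-level
fold differences are max/min ratios with the gene labels.  Simple
regressions are OLS with R^2 as squared Pearson correlation.  No
multiple-testing correction is applied; p-values are reported raw.

The joint analysis enumerates all 2^p - 1 predictor subsets; the best
model is the highest adjusted R^2 (ties: fewer predictors, then
lexicographic order).  Relative importance uses the LMG decomposition,
computed from subset R^2 values with the combinatorial weights
|S|! (p-|S|-1)! / p! — algebraically identical to averaging sequential
R^2 increments over all p! orderings, which the tests verify against a
literal all-orderings reimplementation.  Shares sum to the full-model R^2
to 1e-10.  Exactly collinear predictors are fit through the pseudo-inverse
(duplicated predictors receive equal shares by symmetry); an error is
raised only for constant predictor columns or underdetermined designs.

## Synthetic cohorts

The generator emulates the study design so each stage can be tested
against known truth; its defaults are the package's study conditions:
16 species, 40 genes of 300 codons, a 150 kb circular genome with two
exact 25 kb inverted repeats (large/small single-copy split 80:20 of the
non-IR sequence), a Yule (pure-birth) rooted topology rescaled to a
root-to-tip height of 0.1 substitutions per site (plastid genes evolve
slowly; this keeps every per-branch dS comfortably below saturation),
mRNA ~ LogNormal(meanlog 2, sdlog 1), omega ~ Uniform(0.05, 0.5), planted
effects beta_distance = beta_mrna = -0.5 on z-scores, and log-normal rate
noise with sd 0.1.

Per-gene rate multipliers follow

    log mu_g = beta_distance z(d_g) + beta_mrna z(log m_g) + eps_g.

mu_g multiplies the *background (synonymous) clock*: because realized
branch lengths count all substitutions and purifying selection suppresses
the nonsynonymous ones, simulated branch lengths are scaled by
mu_g (P_S + omega_g P_N), which makes E[dS] proportional to mu_g — the
natural reading of "background substitution rate".  Per-gene
position-specific nucleotide frequencies are Dirichlet perturbations
(concentration 30) of an AT-rich base (0.3/0.2/0.2/0.3), so amino-acid
composition — and hence the tolerance covariate — varies across genes
emergently rather than being set directly.  Genes are placed in evenly
spaced slots in the single-copy regions with a per-species jitter of the
start position, so the cross-species average distance is meaningful.
Because the joint distribution of position and expression in real
plastomes is not something the generator asserts, the correlation between
the two planted covariates defaults to zero and is exposed as a knob
(`covariate_correlation`, a Gaussian-copula correlation between z(d) and
z(log m)).

The generator is a pure function of (config, seed): per-gene streams are
derived by fixed offsets from the cohort seed, so per-gene output is
stable under reordering.  What it does **not** emulate: indel evolution
(deliberately; real plastid alignments contain too few indels to matter),
among-site rate variation, realistic codon usage or taxon sampling, IR
sequence divergence (planted repeats are exact copies), and any
correlation between a gene's simulated alignment and the nucleotide
sequence at its genomic location.  Passing tests therefore demonstrate
correctness of the machinery and recoverability of planted effects at
desk scale — not that real plastomes satisfy the planted model.

## Problem sizes used in the checks

The test battery runs at reduced scale chosen as a compromise between
statistical resolution and a desk-scale runtime: parameter recovery uses
20 genes x 16 taxa x 300 codons; the replicated direction-recovery check
uses 100 cohorts of 6 genes x 16 taxa x 60 codons; geometry checks use
50 genomes of 60 kb with 9 kb repeats.  The acceptance script runs the
full pipeline on a 40-gene cohort at 150 codons per gene.  Bands and
seeds in the tests were frozen after pilot runs at exactly these sizes.

## Known limitations

* Branch lengths at the identifiability ridge around the root (the two
  root-adjacent branches of a reversible model constrain only their sum)
  are reported as the optimiser leaves them; totals are unaffected.
* The codon-column trimming rule is strict ("more than 90% gaps"), chosen
  as this package's contract; other trimming tools differ at the exact
  boundary.
* Fitted dS for genes with essentially no variation is undefined; the fit
  refuses all-identical alignments rather than returning zeros.
* LMG enumeration is limited to 8 predictors (subset enumeration to 12),
  which covers this analysis comfortably.
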