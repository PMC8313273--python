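# Methods

This note records the models the package implements, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing a run.

## SparCC correlation inference

`sparcc_correlations` estimates basis (absolute-abundance) correlations from
compositional counts. For each of `n_fraction_resamples` (default 20, the
reference implementation's default) a fraction matrix is drawn per sample
from Dirichlet(counts + 1); the uniform pseudocount handles zeros and is the
algorithm's published prior. The variation matrix T_ij = Var[ln(x_i/x_j)] is
computed from the log covariance, the basis variances solve
sum_j T_ij = (m-2) w_i + sum_j w_j, and
rho_ij = (w_i + w_j - T_ij) / (2 sqrt(w_i w_j)). Because strongly correlated
pairs violate the sparsity assumption behind that linear system, the single
strongest pair with |rho| above `exclusion_threshold` (default 0.1) is
removed from the system and the variances re-solved, for at most floor(m/3)
rounds. The reported matrix is the per-entry **median** over resamples
(robust to occasional degenerate resamples); raw values outside [-1, 1],
which the quadratic can produce when a basis variance is underestimated, are
clipped and counted in a diagnostics log. At least 4 OTUs are required —
below that the basis system is underdetermined.

Pseudo-p-values (`sparcc_pvalues`) come from a permutation bootstrap: each
OTU column is permuted independently across samples (destroying all
between-OTU association, preserving marginals), the full estimate is re-run,
and the two-sided p is (1 + #{|rho_boot| >= |rho_obs|}) / (1 + n_bootstrap).
With the minimum 99 bootstraps the p-grid resolves alpha = 0.05.

## Networks, topology, MCODE, PCIT

Networks are built at |rho| > 0.65 (the threshold is exclusive, matching the
"greater than" convention). Isolated nodes stay in the node set with an
`isolated` flag; GraphML export omits them by default, which is the usual
rendering convention, and `avg_edges_per_node` therefore divides 2E by the
non-isolated node count (a switch restores division by all nodes). Stability
is the percentage of negative edges (negative correlations read as
competition); complexity is edges per node; the clustering coefficient is
the mean local coefficient over nodes of degree >= 2; density is loop-free
2E/(V(V-1)).

MCODE runs on the unsigned graph (module detection is defined for unweighted
graphs; signs stay as edge metadata). Stage 1 weights every vertex by
k_max x density of the maximal k-core of its closed neighbourhood; stage 2
grows a complex from the highest-weighted unused vertex, admitting
neighbours whose weight is at least seed_weight x (1 - node_score_cutoff);
stage 3 (haircut) reduces the complex to its 2-core. Defaults
(node_score_cutoff 0.2, haircut on, fluff off, k_core filter 2, min size 3)
are the plugin's published defaults. Modules are scored density x size,
sorted descending; ties in vertex weight break by node ID, so output is
deterministic. Module identity across per-stage networks is *not* asserted;
`match_modules` reports the Jaccard overlap matrix and leaves the judgement
to the analyst.

PCIT is provided as an optional edge filter and is off by default: the
default pipeline thresholds SparCC correlations directly. For every triad
the three first-order partial correlations are computed, the tolerance is
the mean ratio of partial to direct correlation, and an edge is dropped iff
some third node dominates it under that tolerance. Triads containing
|rho| = 1 are skipped (singular partials). Note the filter's behaviour
depends on correlation strength: an indirect chain edge at moderate
correlations (about 0.5) is removed, while at very strong correlations the
tolerance shrinks enough that it survives — a property of the published
rule, not of this implementation.

## Co-abundance groups

The retention rule "pairs with correlation above 0.5" is read as an
OTU-retention rule — keep OTUs having at least one partner with rho > 0.5 —
because Ward clustering needs a complete distance matrix over the retained
set; the full 1 - rho matrix (sub-threshold entries included) is then
clustered. The alternative reading (saturate sub-threshold distances at 1)
is available via `sub_threshold_to_one`. Negative correlations give
distances above 1; they are kept as-is (a valid dissimilarity, and the
stated transform). Linkage is scipy's Ward on the dissimilarity (Ward.D2
semantics, the modern hclust default). The tree is cut into `n_cags`
clusters; in auto mode the scan starts at the largest candidate count and
returns the first (largest) cut in which every multi-member CAG validates.

Validation treats OTUs as observations and their relative-abundance profiles
across samples as coordinates — the only reading under which "significance
of each CAG" with Bray-Curtis is computable. Membership (this CAG vs. the
other retained OTUs) is tested by two-group PERMANOVA; with the
Gower-centred matrix G the model sum of squares reduces to
(1/n1 + 1/n2) m'Gm, so all permuted statistics come from one matrix product.
When the number of distinct label configurations C(n, n1) fits within the
permutation budget the **exact** permutation distribution is enumerated
instead of sampled; this matters for small retained sets, where random
permutations otherwise duplicate the observed split (or its complement,
which has an identical statistic) and make the p < 0.005 acceptance line
unreachable. A CAG is acceptable at p < 0.005 with 999 permutations, so a
null CAG is accepted with probability 4/1000 — the calibration the tests
check. Single-member CAGs are skipped with a log note.

Group comparisons are two-sided Wilcoxon rank-sum (Mann-Whitney) on
per-sample CAG abundances, no multiplicity correction by default (the
comparison-wise convention of the analysis style this package reproduces);
Benjamini-Hochberg is a flag.

## Diversity and PERMANOVA

Chao1 is the bias-corrected estimator S_obs + F1(F1-1)/(2(F2+1)) (defined
when F2 = 0); the classic form is a flag. Shannon is in nats (mothur's
convention); log2 by flag. Faith's PD — the branch length of the minimal
subtree spanning the observed leaves and the root — is computed by a direct
postorder traversal so that multifurcating (e.g. star) trees are valid
input; on bifurcating trees it is tested equal to scikit-bio's
implementation. Unweighted UniFrac is scikit-bio's, cross-checked in the
tests against an independent branch-enumeration oracle on exhaustive
presence patterns. Bray-Curtis defaults to relative abundances (counts by
flag).

PCoA eigendecomposes the Gower-centred -D^2/2; coordinates are eigenvectors
scaled by sqrt(eigenvalue); negative eigenvalues are reported but excluded
from the proportion-explained denominator; each axis's first nonzero loading
is made positive, for reproducibility.

PERMANOVA partitions the Gower-centred total sum of squares sequentially
(Type I) in the user-given factor order — the adonis default, and the
default order here is batch, stage, farm, genetics; a marginal
(one-factor-at-a-time) mode is available. p-values use free permutation of
sample labels, p = (1 + #{F_perm >= F_obs}) / (1 + n_perm). Repeated
measures (the same animals across stages) are deliberately ignored by free
permutation, matching the standard adonis usage this mirrors; a
within-animal restricted mode is a natural extension but is not implemented.
Aliased factors and single-level factors are rejected with named errors.

## LDA effect-size screening

Features are scaled per sample to a total of 1e6 (the LEfSe convention), so
a score threshold of 2.0 means a between-class effect of about 100 parts per
million. A Kruskal-Wallis gate at `alpha` (default 0.05) is followed by
`n_boot` (default 30) bootstrap iterations, each subsampling two-thirds of
every class and fitting a regularized linear discriminant (class means,
pooled within-class covariance plus a 1e-6-relative ridge). The per-feature
effect in one iteration is the arithmetic mean of (a) the magnitude of the
between-class mean difference the unit LDA axis attributes to the feature
and (b) the raw between-class mean difference; for more than two classes the
extreme spread of class means plays the role of the difference. The score is
log10 of the bootstrap mean, floored at 1 (scores are therefore >= 0). The
subclass (pairwise Wilcoxon) stage of the original tool is omitted: the
designs here are one-factor with no subclass structure. Exact numeric parity
with the online tool is not promised; the estimator is validated by planted
recovery and null calibration. Known behaviour worth stating: with hundreds
of features the Kruskal-Wallis gate alone passes about 5% of null features,
and among reasonably abundant taxa the LDA > 2.0 gate removes only part of
those, so the *family-wise* chance of at least one null biomarker per
dataset is high — the tool's well-known permissiveness. The tests therefore
assert the per-feature rate (<= 5% of null features flagged per dataset),
not family-wise control, which this procedure does not provide.

Spearman pathway-taxon correlation is scipy's tie-corrected rho with the
t-approximation p; constant vectors yield missing entries rather than
errors; Benjamini-Hochberg is a flag.

## Synthetic data generator

The generator emulates the data structure the analyses assume, one latent
layer at a time. Per sample s and OTU j the latent log abundance is

y[s,j] = b[j] + latent_sd * e[s,j] + stage term + group term

with b[j] ~ N(0, base_logmean_sd) a fixed baseline (default sd 1.5 ln-units,
a realistic 16S spread), e unit-variance noise equi-correlated at
`block_correlation` within each planted block and independent elsewhere,
`latent_sd` = 2.0 ln-units of per-sample biological fluctuation, a
one-period sinusoid over the four ordered oestrus stages (random per-OTU
phase, amplitude `stage_amplitude`) for stage OTUs, and +-group_log2fc*ln 2
for NO samples on group OTUs (optionally a whole block via
`group_effect_block`, which makes the planted block a group biomarker for
end-to-end tests). Composition is softmax(y); counts are
Dirichlet-multinomial at `depth` with concentration (1-theta)/theta.

Two generator choices deserve their rationale. First, `overdispersion`
defaults to 1e-4, i.e. nearly multinomial: dispersion estimates fitted to
real 16S tables (~0.01-0.05) absorb *all* biological variance, but here the
biological variance is explicit in the latent field, so theta represents
only residual library/technical noise; a larger theta would double-count
biology as noise and attenuate every correlation the generator promises to
plant. Second, planted OTUs (blocks, stage, group) take the upper half of
the baseline distribution: structure planted in taxa too rare to observe at
the configured depth carries no recoverable signal and would be excluded by
the standard abundance filters anyway — a benchmark plants signals where
data exist. Unplanted OTUs keep the full baseline distribution and serve as
the null background.

The sample layout is a full stage x group grid (default 22 samples per cell,
the emulated study's per-stage size) with rotating batch/farm/genetics
labels and repeated animal IDs across stages. The tree is a random
coalescent (only topology and branch lengths matter for PD/UniFrac);
taxonomy labels come from cutting the coalescent merge history at fixed
clade counts per rank, so genera and families are monophyletic by
construction. Pathway tables are weighted sums of linked OTU relative
abundances plus Gaussian noise clipped at zero.

What the generator does **not** emulate: sequencing error and chimeras, true
zero-inflation beyond sampling zeros, phylogenetic signal in abundances
(taxonomy is independent of the planted blocks), batch effects with real
structure (batch labels are pure noise), and uneven library sizes (all
samples share one depth). Passing tests therefore demonstrate correctness of
the estimators and calibration of the permutation machinery under the stated
model — not robustness to every artefact of real amplicon data.

## Pipelines, seeds, determinism

Both orchestrated analyses derive every stochastic stage's seed from the
master seed by a fixed counter scheme (seed_k = (master*1000 + k) mod 2^31),
so stages can be rerun in isolation; the manifest records the tool version,
a config hash (excluding the output directory), all derived seeds, every
output file and one log note per stage with row counts. Numeric tables are
written with a fixed %.10g float format, making repeated runs byte-identical
— which the acceptance script verifies. Metadata I/O disables pandas's
NA-sniffing so that a group literally named "NA" (as in normal-cycle
animals) survives a round trip.

The two filter regimes (0.01% abundance / 10% prevalence for diversity;
0.05% / 20% for networks and CAGs) are applied independently to the input
table, and per-stage networks re-filter within each stage's sample subset,
so each stage has its own OTU set. The per-OTU abundance statistic for
filtering is the mean across the analysis's samples (max by flag) — the
community convention where the published phrasing does not choose.

## Problem sizes used by tests and the acceptance script

Recovery and calibration run at: 50 OTUs / 200 samples / depth 20,000 for
SparCC recovery (one 5-OTU block at 0.8) and the module/CAG recoveries (two
8-OTU blocks at 0.9); 100 samples x 50 independent OTUs with 99 bootstraps
for pseudo-p calibration; 500 null datasets of 40 samples for PERMANOVA
calibration (199 permutations each); 2,000 random CAGs (30 OTUs x 20
samples, 999 permutations) for the validation null; 100 (tests) or 60
(acceptance script) replicates of an 80-sample, 200-feature screen for the
effect-size calibration; and an 80-OTU, 160-sample end-to-end run for both
pipelines. These sizes keep a full validation pass in the minutes range on
one CPU while leaving every asserted margin wide.

## Known limitations

- SparCC estimates are attenuated a few hundredths below the planted basis
  correlation by compositional closure and count noise even at depth 20,000;
  the acceptance margin (mean absolute error <= 0.15) absorbs this.
- Auto-selection of the CAG count maximises the cut subject to validation;
  it does not optimise any clustering quality index, and with small retained
  sets it typically returns few, large CAGs.
- The LDA effect size is a faithful re-derivation, not a bit-exact port of
  the original tool.
- PERMANOVA's free permutation ignores repeated measures; effect sizes for
  within-animal factors are interpretable, their p-values anticonservative.
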