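# Methods

This note documents the models, statistical procedures, parameter choices
and known limitations of `temporadt`, in the order the pipeline runs them.

## Experimental design assumed

Two fields — well-watered (W) and progressive drought (D) — sampled at five
drought time points (T1–T5) and one recovery point (R, after rewatering),
for a panel of genotypes split into two equally sized groups of contrasting
drought tolerance. Expression is on the FPKM scale; a gene is "expressed"
when FPKM > 0.001 in at least one sample (a flag, never a row filter).
Agronomic traits (biomass, yield per plant, dead-leaf ratio) are measured
per genotype under both fields; physiology (osmotic potential, H2O2) per
genotype × field × time point with replicates.

## Tolerance index and grouping

DTI = (P_d/P_W)·(P_d/P_ad) with P_ad the panel mean of the drought-field
trait. The index is unitless and invariant to common rescaling; the mean of
P_d/P_ad over the panel is 1 by construction. Grouping is a median split on
DTIB — on the packaged reference trial this reproduces the published 6/6
assignment exactly, whereas a largest-gap split does not; exact median ties
break by DTIY, then genotype id, and explicit labels always override.

Trait statistics: Welch (unequal-variance) *t* between groups — the design
only calls for an "independent t test", and Welch is the safer default;
one-way ANOVA across the drought time course with Student–Newman–Keuls
stepwise letters. SNK tests ranges of sorted means against studentized-range
quantiles at span-dependent critical values, never testing inside a range
already declared homogeneous; unbalanced cells use the harmonic mean n, and
letters come from the maximal non-significant ranges (compact letter
display). Two constant samples with equal means give p = 1 by convention.

The exact correlation significance threshold `critical_pcc(n, α)` inverts
the correlation t-test: r* = t*/√(df + t*²) with df = n−2. For n = 12,
α = 0.05 this is 0.576; feeding r* back through the t-test returns α to
1e−6, which the tests assert.

## Differential expression and the two filters

Replicated libraries: two-sided Welch *t* per gene on log2(FPKM + c),
c = 0.01 (one decade below the expression floor; configurable), BH FDR
across expressed genes within each genotype × time-point contrast. DEG ⇔
FDR < 0.05 and |log2FC| ≥ 1. Single pooled libraries: the gene-wise null
spread is the standard deviation of that genotype's adjacent
well-watered-time-point log-ratios (stage drift + technical noise, the only
replication-free variance estimate the design affords), a z-test gives p,
and DEG ⇔ p < 0.05 and |log2FC| ≥ 1. Degenerate gene-wise spreads fall back
to the genotype median. This caller is a deliberately simple, pluggable
stand-in for count-based tools: the pipeline's contribution is downstream
of DEG calling, and externally computed p/log2FC tables can be substituted.

Development filter: a gene significant (same test, same thresholds) between
any *adjacent* W pair (W1↔W2 … W4↔W5) is development-dependent. By default
the exclusion is panel-wide (a gene flagged in any genotype is removed
everywhere): stage regulation is a property of the gene, the flag's false
positive rate at these thresholds is effectively zero, and per-genotype
exclusion would let a gene missed by the flag in two genotypes slip through
the frequency filter. `dev_exclusion="genotype"` restores the
per-genotype behavior.

Frequency filter: a (gene, time point) DEG must appear in ≥ 2 genotypes;
the filter is idempotent and only removes. DRG = final DEG at any of
T1–T5; RRG = final DEG at R; the labels can coexist. The recovery contrast
is R(D) vs R(W) when well-watered recovery samples exist, else R(D) vs the
T5 W baseline. Shared-DRG ratios between genotypes are Jaccard
coefficients; genotype dendrograms use Euclidean distance on 0/1 DRG
vectors with average linkage.

## Group dynamics

A gene joins a group's DEG set at t when it is a final DEG in ≥ 1 of the
group's genotypes at t (the frequency rule has already acted panel-wide);
common / tolerant-specific / susceptible-specific labels partition the
union. Group-different genes: Welch *t* on per-genotype log2FC at a time
point, flagged at p < 0.05 with the larger-|mean| group recorded. Temporal
clustering: average-linkage agglomerative clustering of T1–T5 mean-log2FC
vectors cut at k = 16 clusters (ids ordered by size, ties by smallest
member id, so the partition is order-invariant). Cross-group profile
similarity uses the ±0.4 correlation bands. Recovery modes enumerate the
3×3 (W5→D5, D5→R) transition classes minus the doubly-unchanged pair, in
the fixed order (up,up), (up,unch), (up,down), (unch,up), (unch,down),
(down,up), (down,unch), (down,down); the unchanged band is |log2FC| < 1,
matching the DEG threshold. The D5→R transition is computed as the
difference of the R and T5 group-mean fold changes, which share the W
baseline.

## Enrichment and temporal typing

One-sided hypergeometric over-representation against the expressed-gene
background (not the whole annotation), BH across tested terms (Bonferroni
available). Typing uses FDR < 0.05 presence over D1–D5 per group:
I identical vectors; II/III single-group; otherwise "initiated earlier" =
smaller first-enriched index and "lasted longer" = more enriched points —
IV/V when one group wins at least one predicate and the other none, VI on
conflicts. The six types partition all drought-enriched terms; swapping the
groups maps II↔III, IV↔V and fixes I and VI (a property test). Terms
enriched only at R are recovery-specific. The classification counter counts
a term once per classification (multi-classified terms are multi-counted,
matching the referenced web tool), with an `unclassified` bucket.

PCoA: Gower-centered squared-distance eigendecomposition; coordinates are
eigenvectors scaled by √λ for positive eigenvalues; negative eigenvalues
(possible for non-Euclidean Jaccard inputs) are reported but generate no
axes. Correspondence analysis: SVD of the standardized Pearson-residual
matrix; total inertia = χ²/n = Σσ², asserted against a direct χ² oracle.

## Tradeoff regions

r_dtib correlates a DRG's per-genotype mean drought log2FC (T1–T5) with
DTIB; r_biomass correlates its mean well-watered FPKM (W1–W5) with biomass
under W; both use the exact |r| threshold at the panel size with *strict*
inequality (a gene exactly at the threshold is not significant).
Osmotic-potential and H2O2 correlations pool all drought-field samples
(replicate-matched to the trait measurements) with significance |r| > 0.4
and p < 0.001; genotype is not partialled out — a documented limitation,
as group structure can inflate pooled correlations. Whether physiology
correlations should use FPKM or fold change is ambiguous in this design;
FPKM is the default and the basis is switchable. The nine-region map is
exhaustive and exclusive over defined correlations and mirror-symmetric
under trait negation (property-tested).

## Coexpression network

Expression basis: log2(FPKM + c) of all drought-field samples of the final
DRGs, both groups pooled (one network). Unsigned soft-threshold adjacency
|PCC|^β with β = 6, the conventional unsigned default. TOM_ij =
(Σ_u a_iu·a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), unit diagonal, verified
against a double-loop oracle at 1e−12. Edge cutoff: on the τ grid
0.01–0.50 (step 0.01), keep nodes with ≥ 1 edge TOM ≥ τ and take the first
τ minimizing density 2E/(n(n−1)) over retained nodes — node filtering makes
density non-monotone in τ, which is what makes the minimum well-defined; a
fixed τ override is honored verbatim. Modules: average linkage on 1 − TOM
over retained genes, cut at 0.99 × the maximal merge height, then clusters
below 30 genes merge into their nearest cluster by mean inter-cluster TOM;
unretained genes are `unassigned`. This is a documented simplification of
dynamic tree cut, not a replication of it. Eigengenes are the first
right-singular direction of the gene-standardized submatrix, zero-mean and
unit-variance over samples, sign-aligned to the mean member profile. Hubs
are exactly the top ⌈0.15·size⌉ by intramodular connectivity (ties by gene
id). Candidates are hubs with (a) a significant tolerance-trait
correlation, (b) membership in a type II/IV enriched term, and (c) a region
outside III/VII. Hormone cross-talk entries are means of pairwise PCCs
between pathway DRGs' group-mean fold-change timelines (T1–T5, R),
computed per group; pathways with < 2 usable DRGs report missing.

## Synthetic-data generator

Log-normal expression with additive log2 effects makes every planted
log2FC exact:

log2 x = baseline (N(3, 1.5²)) + genotype effect (N(0, 0.15²)) + tradeoff
baseline shift + module latent factor + condition×time effect + development
stage effect + replicate noise (N(0, 0.15²)).

Gene classes (fractions of 2000 genes): common 10% (split over the
temporal-type programs I/IV/V/VI with per-group kernels), tolerant-specific
5% (type II, early kernel), susceptible-specific 8% (type III, transient
kernel — the imbalance mirrors acclimation-heavy susceptible responses),
recovery-only 3%, development-dependent 2%, unexpressed 1%, the rest null.
Effects draw |log2FC| from {1.25, 1.5, 2, 3}, 60% up. Development decoys
follow a stage profile stepping by 2.0 (twice the DEG threshold) between
adjacent W points, with drought samples lagging one stage — so they show a
spurious D-vs-W difference that the adjacent-W filter must catch.

Replicate noise was set by a Monte-Carlo calibration of the
generator/caller pair: at 0.15 the Welch/BH caller detects planted
|log2FC| = 2 with sensitivity ≈ 0.99 at n = 3 (at 0.25 the
Welch–Satterthwaite degrees of freedom collapse toward 2 on unlucky draws
and sensitivity falls to ~0.81, which would say more about small-n t-tests
than about the pipeline).

Latent tolerance u is fixed per group (tolerant 0.65–0.95, susceptible
0.05–0.35): drought biomass retention is 0.25 + 0.55u (yield 0.08 + 0.65u),
dead-leaf ratio 0.55 − 0.30u, all with small log-normal noise, so the DTIB
ordering recovers u (Spearman ≥ 0.8 over seeds) and the median split
recovers the planted groups. Osmotic potential follows the tolerance
program's mean expression in drought samples (500 + 60·signal ± 12) and
H2O2 the acclimation program's (0.30 + 0.06·signal ± 0.02), reproducing the
tolerant-higher-osmotic / susceptible-higher-H2O2 pattern.

Planted coexpression modules: the non-tradeoff tolerance program, the
non-tradeoff acclimation program, and one growth-coupled module holding the
tradeoff genes of both programs. Module activity is one latent value per
(module, genotype) (sd 2.0), loaded with the sign of each member's effect
and applied to *both* fields so it cancels exactly in every contrast; the
activity vectors are orthogonalized against the constant, the group
contrast, the biomass axis and each other, because chance correlations
among 12-genotype vectors would otherwise blur module boundaries under the
unsigned |r|^6 adjacency. Tradeoff genes instead cohere through their
±0.8·z(biomass) baseline shift; the two tradeoff half-programs are strongly
anti-correlated through that shared axis, and an unsigned network
necessarily places anti-correlated genes together — hence one planted
growth-coupled module, which is the biologically honest label. Tradeoff
genes' drought response also scales with u (0.5 + u for the tolerance side,
1.5 − u for the acclimation side), which drives their DTIB correlations
into regions III/VII.

GO structure: 6 terms per temporal type (25 genes: 20 from the program,
5 background), 3 recovery-only terms, 30 background terms; classifications
assigned cyclically with some terms multi-classified and some unmapped.
Hormone pathways are 8 disjoint 12-gene sets, half drawn from responsive
programs. A separate `two_block_network` fixture (2 × 60 genes, 80
samples, factor loadings of random sign, noise sd 0.35) provides the clean
two-module benchmark for the network detector.

**What the generator does not emulate** — count-level sampling noise,
library-size and transcript-length bias, dispersion–mean coupling, partial
group overlap of programs, GO-DAG structure (annotations are flat maps),
correlated traits beyond the planted couplings, genotype × environment
interactions beyond the single latent u. Passing tests therefore
demonstrate internal correctness and recoverability under the planted
model, not performance on real sequencing data.

## Problem sizes and numerical choices

The default synthetic study is 2000 genes × 12 genotypes × 6 time points ×
2 fields × 3 replicates (432 samples); a full pipeline run takes well under
a minute on one CPU, and the test suite uses 300–400-gene configurations
for Monte-Carlo loops. Ties break deterministically everywhere (first grid
point for the density minimum, gene id for hub ranks and cluster ids);
all randomness flows from a single integer seed through
`numpy.random.default_rng`; zero-variance inputs yield NaN correlations and
are excluded from region calls rather than propagated.

## Known limitations

The DEG caller is a normal-theory stand-in, not a count model; SNK letters
assume approximate normality within cells; the density-minimum cutoff rule
is an interpretation of a procedure that is under-specified in the
literature it comes from (our operationalization — retained-node
denominator, first-minimum tie break — is stated above); module detection
approximates dynamic tree cut with a fixed-height cut plus small-cluster
merging, and on hard instances (strong cross-module correlation) it can
merge planted modules at the fixed 0.99 cut; pooled physiology correlations
do not adjust for group structure.
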