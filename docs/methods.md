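# Methods

## The analysis in brief

The package implements a covariate-adjusted epigenome-wide comparison of DNA
methylation between the two clinical forms of severe acute malnutrition —
edematous (ESAM, kwashiorkor and marasmic-kwashiorkor) and non-edematous
(NESAM, marasmus) — together with the downstream machinery that gives such a
comparison biological meaning: spatial clustering of differential CpGs,
gene-set and disease-trait enrichment, condition-dependent cis-meQTL
classification, and methylation–expression correlation. All components are
exercised end to end on a synthetic-data generator with a known truth ledger.

## Single-site model

Methylation is carried as beta values (methylation fraction, strictly inside
(0,1)) and analysed as M values, `M = log2(beta/(1-beta))`. Per probe *i* the
model is

```
M_i = C a + Y b + e
```

with `C` the covariate matrix (age, sex, and a leading principal component of
the transformed M matrix, or MDS ancestry coordinates supplied as plain
columns), `Y` the ESAM/NESAM indicator, and `e` iid Gaussian error. Before
fitting, each probe's M vector is mapped through a rank-based inverse normal
transform using the Blom constant for every sample size: ranks (average on
ties) go to normal quantiles at `(r − 3/8)/(n + 1/4)`. This package applies
the 3/8 offset uniformly — a deliberate convention; some reference
implementations switch to a 1/2 offset above n = 10, which changes transformed
values by well under 0.01 at the sample sizes involved. The transform makes
the per-probe t test robust to the bimodal, heteroscedastic marginals of
array methylation while preserving ranks.

Inference on the group coefficient uses a two-sided t with `n − k` residual
degrees of freedom (k = number of design columns). Because effect sizes are
conventionally reported in beta units, a second OLS with the identical design
is run on the untransformed beta scale; its group coefficient is the reported
`beta_slope` (covariate-adjusted ESAM − NESAM methylation difference) and
supplies the direction label. On monotone transforms with covariates
orthogonal to the group the two slopes agree in sign; tests check this.

Multiplicity: Benjamini–Hochberg q-values for FDR statements, and a
family-wise threshold `alpha/m` (printed at two significant digits) for
Bonferroni statements. The genomic inflation factor is
`lambda = median(chi2_1 deviates of the p values) / 0.4549`; cohort-specific
p values can be deflated by dividing the chi-square deviates by lambda
(applied only when lambda > 1, the usual genomic-control convention, inside
the concordance report; the raw `lambda_adjust` operation accepts any
positive lambda). Cross-cohort concordance removes a caller-supplied list of
age-sensitive probes first (used when age cannot serve as a covariate),
counts direction agreement against a two-sided exact binomial null of 0.5,
and counts probes lambda-adjusted significant in both cohorts.

## Differentially methylated clusters (DMCs)

Methylation at neighbouring CpGs is spatially correlated, so single-probe
hits are consolidated: probes whose `beta_slope` lies strictly inside the
open interval (−0.05, +0.05) are removed (their effect direction is
ambiguous at the margin — a slope of exactly ±0.05 is retained, a choice the
package documents and makes configurable); the retained probes are scanned
left-to-right per chromosome and chained whenever the gap to the previous
retained probe is ≤ 10,000 bp and the effect sign matches. Removed probes
neither bridge nor break chains (filtering precedes binning). Cluster spans
are min/max member positions with no flanking extension; singletons are
legal. Filtered "marginal" probes falling within a cluster span ± the gap are
counted retrospectively (`n_marginal_nearby`, flagged when > 2) but never
alter membership.

The cluster test repeats the single-site regression with the per-sample mean
of member probes' transformed M values as the response and a Bonferroni
threshold of `alpha / n_clusters`. For a singleton this reduces exactly to
the single-site test, which the suite asserts. The scan is verified against a
naive maximal-run enumeration oracle on 1,000 random instances.

## Enrichment machinery

*Gene mapping.* Genes overlapping or within 10 kb of a cluster span are its
candidates ("within 10 kb" is ≤ 10,000 bp, 1-based inclusive coordinates
throughout). Without gene coordinates the probe-level gene links serve as a
fallback.

*Context enrichment.* Hypergeometric tails in both directions per
gene-context category (TSS1500, TSS200, 5'UTR, 1stExon, Body, 3'UTR, IGR),
comparing the probes inside significant clusters with all tested probes.

*EFO projection.* Candidate genes are joined to a GWAS-catalog-style table
(EFO trait, gene, genome-wide-significant SNP count); traits hit by ≥ 2
candidates are retained with the SNP counts as cell scores. The resampling
null redraws the candidate count from a caller-chosen universe (two presets
mirror common choices: all array-linked genes, or the catalog∩array subset)
and records the joint tail `P(G ≥ g_obs and E ≥ e_obs)` plus per-trait
recurrence. Empirical p values are reported both as raw fractions (the
conventional print) and as `(b+1)/(n+1)` (never zero, always valid).

*HPO overlap Z.* Overlap of candidates with a phenotype gene set versus
size-matched random draws; the null overlap of a uniform without-replacement
draw is a hypergeometric count and is sampled as such (statistically
identical to redrawing gene sets, considerably faster, still seeded and
bit-reproducible). Z = (obs − mean)/sd with a degenerate-null flag when
sd = 0.

*SGO–KGO score.* Study gene ontologies (SGOs, enriched by the DMC genes) and
kwashiorkor-phenotype gene ontologies (KGOs, enriched by HPO-linked genes)
are each ranked ascending by p; a term's quartile value is 1, 0.75, 0.5 or
0.25 (best quartile first, bucket `ceil(4·rank/n)` with average-rank ties —
tie handling is this package's choice, as no convention is standard). The
quartile score of an SGO is the product of its two quartile values, zero if
it is absent from the KGO list; the proportion score of an (SGO, phenotype)
pair is the fraction of the phenotype's genes mapping to the SGO; the final
score is the arithmetic mean of the two and lies in [0, 1] (property-tested
under fuzzing). Ontology enrichment p values themselves come from a generic
hypergeometric over-representation test over user-supplied gene sets.

*Effect size by context.* Kruskal–Wallis omnibus on |beta_slope| across
contexts plus pairwise Dunn z tests with joint-rank tie correction, reported
unadjusted by default (Bonferroni/BH optional).

## cis-meQTLs and nutrition sensitivity

Genotype QC: per-sample then per-SNP missingness (> 2% removed), Hardy–
Weinberg exact test (conditional on allele counts, log-space enumeration;
p < 1e-3 removed), MAF < 0.05 removed; relatedness/inbreeding exclusions are
accepted as a precomputed sample list. SNP–CpG pairs form within 10 kb on the
same chromosome (distance to the cluster span for cluster targets).

Per pair, within a sample subset, two OLS models on the transformed M value:

* additive: `covariates + dosage` — slope `beta1`, Wald/t `p_main`;
* interaction: `covariates + dosage + group + dosage×group` — `p_interaction`
  on the product term, with per-group slopes reported.

A pair is **nutrition sensitive** when it passes the acute-phase (DC) meQTL
screen (`p_main ≤ 0.05`, pooled-DC reading; a per-group screen is available
by flag), shows a DC interaction (`p_interaction ≤ 0.05`), and shows no such
interaction among recovered (DL) samples (`p_interaction > 0.05`); pairs
passing the screen but failing the pattern are insensitive, everything else
untested. A stringent tier additionally requires DC `p_interaction < 1e-4`.
Note the classifier's definition caps its own sensitivity near 95%: even a
perfectly powered pair fails whenever the null DL interaction fluctuates
below 0.05, which happens 5% of the time by construction. Overlap of the
sensitive/insensitive sets with an external reference catalog is tested with
a two-sided Fisher exact test (point-probability rule by default; tail
doubling available).

## Methylation–expression correlation and power

Genes count as expressed when their mean expression is at least twice the
grand mean of the antigenomic control probes (boundary inclusive). For each
CpG inside a significant cluster and each expressed gene within 10 kb,
Spearman correlations are computed on both the beta and M scales across the
paired samples; p values use the standard t approximation (adequate for the
n = 20 pairing here; an exact-permutation option would only matter below
n ≈ 10). Per-context sign structure is tested with a two-sided Wilcoxon
signed-rank on the coefficients — exact for n ≤ 25 without ties, normal
approximation with continuity correction otherwise.

The post-hoc power of the two-sided test of ρ = 0 at sample size n is
computed exactly for a bivariate normal population: the critical sample
correlation is `t_crit/sqrt(n−2+t_crit²)` from the null t transform, and
power integrates the exact non-null density of the sample correlation —
the Gaussian-hypergeometric form

```
f(r) ∝ (1−ρ²)^((n−1)/2) (1−r²)^((n−4)/2) (1−ρr)^((3−2n)/2)
       · 2F1(1/2, 1/2; n−1/2; (1+ρr)/2)
```

— over the rejection region by adaptive quadrature (absolute error well
below 1e-6). At ρ = 0 the power equals the level; at n = 20 it evaluates to
53% for |ρ| = 0.45 and 91% for |ρ| = 0.65 (whole-percent reporting), and a
Monte-Carlo sampler of r serves as the independent oracle in the tests.

## The synthetic generator

`simulate_study` draws, per probe, a baseline M value from N(0, 2.0) (a
logit-normal baseline beta — wide, covering the hypo/hyper range of array
data), lays probes down cluster-first (blocks of 2–10 probes, intra-block
gaps 50–2,000 bp, inter-block gaps > 10 kb plus an exponential tail with
50 kb mean, so that genuine blocks chain under the 10 kb rule and distinct
blocks never do), and builds a sample sheet with acute (DC) children
(default 150 per disease group, ages 0.5–5) and recovered (DL) adults
(default 25 per group). Group effects are injected on the beta scale —
`true_effect_beta` (default 0.05, the magnitude the analysis is designed to
detect) with one shared sign per affected block, hypomethylation in ESAM
with probability 0.9 — and confined to DC samples; betas are clamped to
(0.001, 0.999) with a logged warning if an effect would leave the valid
range. Covariates act on the M scale (defaults: age 0.02 M/yr, sex 0.1,
PC1 0.2); residual noise is Gaussian on the M scale with default SD 0.3,
the middle of the range of covariate-adjusted M-value residual SDs typical
of 450K-style data (individual analyses may set 0.5 to stress power, as the
recovery characterization below does).

`simulate_genotypes` draws Binomial(2, MAF) dosages (MAF uniform on the
configured range), places each planted SNP within 10 kb of its target CpG,
and doses the target's M values: additive pairs in all samples,
interaction-only pairs in acute ESAM samples only (so their additive slope
in the reference group is 0 by construction). `simulate_genesets` draws
EFO/HPO/ontology universes uniformly under the null with optional planting
of hit genes; `simulate_expression` gives probe-linked genes expression that
tracks their block's mean methylation with a random sign (regulation is
bidirectional in real data) and emits antigenomic control probes around a
fixed background level.

A single seed drives everything; per-component generators are spawned
deterministically from it (NumPy `SeedSequence`/PCG64), so equal seeds give
bit-identical matrices across platforms. Every simulation returns a truth
ledger (differential probes with block ids and signs; planted pairs with
kinds and slopes).

What the generator does *not* emulate — and hence what passing tests cannot
attest about real data: cell-composition mixtures, batch/chip structure,
probe-type (Infinium I/II) effects, linkage disequilibrium between SNPs,
missing values (core matrices are complete; real-data gaps must be handled
upstream), and spatial correlation of noise within blocks beyond the shared
mean shift.

## Operating characteristics (as computed by the suite and acceptance script)

* Null calibration: 10,000 null probes at 150/group give an empirical
  type-I error inside the 95% binomial interval around 0.05 and lambda
  within [0.9, 1.1].
* Planted recovery: with the 0.05 beta shift, M-noise 0.5, 150/group, ~85–90%
  of true DMC probes are recovered at FDR < 0.01 with ≈0 false discoveries
  among the nulls.
* Nutrition-sensitive classifier: a planted interaction-only pair at
  0.4 M/allele, MAF 0.3–0.5, 60 DC samples/group is flagged in roughly 92%
  of replicates — close to the ~95% ceiling imposed by the classifier's DL
  null condition.

Problem sizes in the test suite and acceptance script (10,000 probes, 100
classifier replicates, 1,000 clustering oracle instances) were chosen so the
full battery completes in a few minutes on a single core while keeping
Monte-Carlo error well inside the asserted margins.

## Numerical conventions and degenerate inputs

Positions are 1-based; distances are `|a − b|` bp; "within 10 kb" is
≤ 10,000 everywhere (gene mapping, expression pairing, SNP–CpG pairing).
Beta/M transforms clamp exact 0/1 to 1e-6 with a warning and round-trip to
1e-12 inside (0.001, 0.999). Constant vectors transform to all zeros (rank
INT) or are flagged untested (meQTL dosage); a constant group indicator
raises. Collinear covariates are dropped with a warning, never the intercept
or the group column. Empty p-value lists, empty probe universes after
filtering, and empty phenotype gene sets raise or flag rather than return
silent numbers. P-values are floored at the smallest positive double rather
than underflowing to 0.
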