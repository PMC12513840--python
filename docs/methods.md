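# Methods

`metabogen` implements the analytic chain of a genome–metabolome association
study — from medication-corrected association scans through trans-stratum
meta-analysis, fine-mapping, pleiotropy classification, effector-gene
scoring, rare-variant burden testing and causal (MR + colocalization)
integration — together with a synthetic-cohort generator that plants known
truth for every stage. This note describes the models, the defaults and the
numerical choices, and what the synthetic validation does and does not show
about real cohort data.

## Synthetic cohort

**Genotypes.** Each individual carries two haplotypes per LD block. A
haplotype's alleles arise by thresholding a latent stationary AR(1) Gaussian
at the allele-frequency quantile, so the latent autocorrelation `ld_decay`
(default 0.9) controls how fast pairwise LD decays along the block and
blocks are independent. Note that thresholding attenuates the genotype-level
correlation below the latent value (a tetrachoric effect): a latent 0.9
yields adjacent-variant genotype r of roughly 0.55–0.7 depending on allele
frequency. Ancestral strata beyond the first receive logit-normal
allele-frequency jitter (SD 0.3, a coarse continental-drift surrogate) and
geometrically weaker LD (`0.8**stratum`), mimicking the shorter haplotypes
of African-ancestry panels. Ultra-rare variants (`rare_fraction`) get MAFs
log-uniform in [2e-5, 5e-4]. Missing calls use the sentinel −1 and are
mean-imputed at association time, matching common dosage practice. The
generator is deterministic: one NumPy `default_rng(seed)` drives every draw.

**Metabolite panel.** Traits follow a linear factor model
`Y = F L' + direct genetic effects + noise`, standardized to unit variance
after generation. The default panel emulates an NMR lipoprotein platform at
desk scale: 12 correlated "lipoprotein-like" factors with 12 primary traits
each (loadings U(0.85, 0.97)) plus one weak secondary loading
(U(0.15, 0.35)) on another factor, and 10 factor-free traits standing in for
small molecules — 154 traits. The factor count and cluster width are a
modeling choice, not an empirical claim about any particular platform; the
cluster width matters because the pleiotropy statistic described below
includes the lead trait's own point, whose leverage only fades in clusters
of a dozen or more traits — mirroring the fact that real pleiotropic mQTLs
hit dozens of correlated measures.

**Planted mQTL modes.** One planted effect per variant, in per-allele SD
units (default scale 0.2):

- *specific*: equal effects on the ≤3 strongest-loading traits of one factor;
- *pathway*: effects on all primary traits of one factor, proportional to
  the trait's implied correlation with the cluster's core trait (1.4× scale,
  keeping the pattern above the sampling noise of the scan);
- *proportional*: injection on the latent factor itself, so every loading
  trait inherits an effect proportional to its loading;
- *disproportional*: geometrically spread magnitudes strictly anti-ordered
  to the loadings, plus one "satellite" trait tied to the cluster only
  through its secondary loading but carrying a near-maximal effect;
- *nonspecific*: random-sign, random-magnitude effects scattered over ~30
  traits across all factors and the independent molecules.

These structures are the geometric archetypes of the five modes; the truth
table records mode, targets and betas per variant.

**Medication.** Treated individuals' baseline traits shift by `med_effect`
(default −0.5 SD on the traits of three "LDL-like" factors, a statin-sized
effect). A configurable fraction of baseline-untreated individuals gets a
repeat visit correlated with baseline at `retest_rho` (default 0.95), a
fraction of whom are newly treated at follow-up — exactly the contrast the
correction regression uses.

**Outcomes.** Binary disease is drawn by thresholding a unit-noise liability
`theta * mediator_trait + direct variant effects + N(0,1)` at the prevalence
quantile. `theta` is the causal quantity MR should recover.

**Rare-variant annotations.** Consequence classes are multinomial
(pLOF-HC 5%, pLOF 5%, missense 45%, synonymous 25%, other 20%); CADD-like
scores are gamma-distributed and lifted for loss-of-function classes;
REVEL-like scores Beta(2,2) for missense; a 5% sliver of "other" variants
carries HIGH VEP-like impact so the high-impact mask is not identical to the
pLOF mask. Genotype-level DP is Poisson(30), GQ clipped normal (60, 10), and
heterozygous allele balance Beta(20, 20) — so QC filters have a known
pass/fail truth.

## Association core

Scans are per-variant ordinary least squares after projecting an intercept
plus covariates out of both trait and genotype (Frisch–Waugh), with
two-sided normal p values; this replaces whole-genome-regression machinery,
which only matters when cryptic relatedness or structure exists — the
synthetic cohorts have none unless planted. The common-variant scan filters
MAF ≥ 0.5%; monomorphic variants are skipped. Scans also emit `mlog10p`
computed from the normal log-survival function, because `-log10(p)`
saturates near 308 in double precision and strong mQTLs routinely exceed it.

Strata are combined by fixed-effect inverse-variance weighting (a
sample-size-weighted Z alternative is provided); variants present in fewer
than two strata are excluded. Heterogeneity is Cochran's Q on chi-square
with k−1 df, flagged at p < 1e-4 across ancestral strata and p < 5e-8
across sexes. Variance explained uses `2 f (1−f) β²`. The metabolome-wide
significance threshold divides 5e-8 by the number of traits (2.0e-10 at 249
traits).

The medication model is fit per sex in individuals untreated at baseline
with both visits: `baseline ~ followup + age + BMI + med(followup)`. The
implied medication effect is the *negated* regression coefficient on the
med indicator; it is subtracted from treated individuals' baseline values.
The estimate is attenuated by the test–retest correlation of the trait
(factor `retest_rho`), which is why the generator's default retest
correlation is high; at `retest_rho = 0.95` a planted −0.5 shift is
recovered as ≈ −0.48. Sexes with fewer than 100 eligible individuals are
skipped with a warning.

## Fine-mapping

Sentinels are clumped into ±500 kb regions, merged when overlapping or
book-ended; anything touching the extended MHC (chr6:25.5–34.0 Mb) is
absorbed into one flagged region that is never fine-mapped.

The Wakefield log approximate Bayes factor is
`0.5·log(1−r) + 0.5·z²·r` with `r = W/(se²+W)`; the prior variance W
defaults to 0.04 (prior SD 0.2 on standardized per-allele effects) and the
computation stays in log space, stable for arbitrarily large |z|. Credible
sets normalize ABFs under a flat prior over region variants and take the
smallest posterior-ordered prefix reaching 95%, with deterministic ties
(position, then variant id).

Multi-signal decomposition is a stepwise conditional analysis on summary
statistics plus LD: repeatedly select the largest conditional |z|
(`z_j|S = (z_j − R_jS R_SS⁻¹ z_S) / sqrt(1 − R_jS R_SS⁻¹ R_Sj)`), stop when
the best conditional p exceeds 5e-8 or the set cap is hit; build one
Wakefield credible set per signal from its conditional statistics
(conditioning on the other leads), drop set members with |r| < 0.1 to the
lead, prune sets whose leads exceed r² = 0.25 against a stronger lead
(smaller marginal p wins; ties break by position — pruning is
order-independent), and report the cap in 2..10 yielding the most surviving
sets. Rank-deficient LD solves are ridge-regularized with a logged epsilon.
This stepwise scheme replaces a full variational sum-of-single-effects
model; it reproduces the downstream set/pruning/concordance logic with far
less machinery, at the cost of less calibrated per-variant posteriors under
heavy multi-signal LD.

A joint-model concordance filter refits all of a region×trait's leads in one
linear model with the scan covariates and retains signals that are
genome-wide significant both marginally and jointly, sign-concordant, and
within ±25% relative effect difference. Lead variants are then merged
across traits into mQTL groups as connected components of the r² ≥ 0.6
graph. Multi-variant credible sets with suggestive evidence (p < 1e-5, a
choice — the threshold is not externally fixed) in another ancestry are
refined by summing per-variant log ABFs across contributing ancestries
(independent-evidence approximation) over the variants observed in all of
them; the refined set may in principle grow and both sizes are reported.

## Pleiotropy classification

For each mQTL group with its associated traits: `q25` is the 25th percentile
of pairwise absolute Pearson correlations among the traits (absolute,
because e.g. particle-size and particle-concentration measures are
anticorrelated by construction yet biologically one cluster), and `statcor`
is the Pearson correlation between association strength (`mlog10p`) and the
squared trait correlation with the lead (most significant) trait. The rule
table at threshold 0.6: n ≤ 3 & q25 ≥ 0.6 → specific; n > 3 & q25 ≥ 0.6 &
statcor ≥ 0.6 → pathway; q25 < 0.6 & statcor ≥ 0.6 → proportional;
q25 ≥ 0.6 & statcor < 0.6 → disproportional; otherwise nonspecific.
Single-trait groups are specific with both metrics undefined; two-trait
groups fall back to the q25 rule alone.

Phenotypic pleiotropy counts distinct ontology parent categories (children
of the ontology roots, reached by iterated parent-walking with a cycle
guard) hit by the group's variants and their r² > 0.8 proxies in a
GWAS-Catalog-dialect table, after pruning rows without a mapped trait,
location, or genome-wide significance and dropping terms descending from
excluded roots (e.g. lipid-measurement branches that would double-count the
panel itself). Fewer than five parents ⇒ phenotypically specific. Unmapped
terms count under an explicit "unmapped" pseudo-parent rather than being
dropped. Category enrichment is per-category logistic regression of the
category-hit indicator on pleiotropic-vs-specific, Bonferroni-corrected,
with zero-variance and separated categories flagged without estimates.

## Effector genes

Up to ten closest genes within ±1 Mb per fine-mapped variant (distance 0
inside the gene body; ties by gene id). Features: distance, closeness rank,
coding consequence on the variant or an r² > 0.6 proxy, per-tissue eQTL
flags, metabolic-database, OMIM and phase-III/IV drug-target membership.
Three putative-true-positive (PTP) sets pair fine-mapped variants of the
cholesterol, lipid and amino-acid metabolite classes with the corresponding
pathway gene sets; variants eligible for several classes go to exactly one
by the fixed priority cholesterol > lipid > amino acid. Pathway membership
defines the labels and is excluded from the features. Each PTP trains a
random forest with variant-grouped 5-fold CV, per-fold majority-class
subsampling and a small hyperparameter grid selected by balanced accuracy;
the 7:3 train/test split is grouped by variant so no variant appears on
both sides (asserted at construction). The effector score is the sum of the
three positive-class probabilities (0–3; the median across classifiers is
kept as a diagnostic column); tiers are moderate ≥ 1.5 and high ≥ 2. Per
variant, the assigned gene set is the top block above the largest gap
between consecutively ranked scores; if all gaps are equal (including
all-flat scores) nothing is assigned and the variant is flagged
low-confidence. Gene-set enrichment utilities (tissue, Mendelian-disease
genes) use a two-sided Fisher exact test with a Haldane 0.5 correction for
zero cells.

## Rare variants

Genotype QC masks calls at DP < 7 (SNVs) / < 10 (INDELs) or GQ < 20,
excludes a variant when a heterozygous carrier's allele balance leaves
(0.25, 0.8) — strictly by default; a fraction-based alternative (>10% of
hets failing) sits behind a flag because the strict reading removes a
variant for a single bad call at biobank scale — and excludes variants with
post-masking missingness > 50%. The operation is idempotent.

Six masks plus a synonymous negative control: M1 high-confidence pLOF; M2
any pLOF; M3 pLOF + missense with CADD > 20 or REVEL > 0.5; M4 pLOF + any
missense; M5 any HIGH-impact variant; M6 missense only; S synonymous —
each crossed with MAF bins < 0.5% and < 0.005% (nested). Burden collapsing
caps the per-individual alt-allele sum at 2, with missing calls counted as
zero. Gene-level p values across masks×bins combine by the aggregated
Cauchy association test `T = Σ wⱼ tan((0.5−pⱼ)π)/Σ wⱼ`,
`p = 0.5 − arctan(T)/π`, with the tangent asymptote `1/(pπ)` below 1e-15
and above T = 1e15 — so k identical p values return exactly p. The
synonymous control is reported but not folded into the gene-level
combination.

Burden and single-variant models are refit with and without a common-variant
polygenic score (per-trait weighted allele sum over lead credible-set
variants); a finding is *robust* only if significant in both models with a
relative effect change ≤ 20%. The exome-wide gene-level default threshold
is 1.2e-8; the simulation-scale screens in the validation experiments use
1e-4, matching their 200-gene scale (thresholds are parameters everywhere).
ExWAS tests single variants at MAC > 5 and reports those with MAF < 0.05%.
Disease burden uses plain logistic regression guarded by a ≥10-carrier
minimum, with separation flagged instead of estimated (no saddle-point or
Firth correction — at the simulated prevalences and carrier counts the
plain MLE is adequate; very rare outcomes would need it).

Allelic series: per rare hit, the distance to the nearest same-trait lead
credible-set variant with flags at <100 kb, <500 kb and >1 Mb, plus a
series flag when an assigned effector gene within 200 kb names the rare
hit's gene.

## Causal integration

Colocalization enumerates the five hypotheses from per-variant Wakefield
log ABFs of two traits on a harmonized grid, accumulated with log-sum-exp:
H4 evidence is Σⱼ ABF1ⱼ·ABF2ⱼ with prior p12 = 5e-6, H3 is
S1·S2 − S12 (guarded log-space subtraction) with p1·p2, p1 = p2 = 1e-4.
Pairs with fewer than 10 shared variants are flagged low-confidence. The
multi-signal wrapper caps outcome decompositions at five signals, and a
locus effect is declared at PP4 ≥ 0.8.

MR: Wald ratio with first-order delta SE per instrument (|z| < 2 flags a
weak instrument); fixed-effect IVW `Σ(bx·by/sy²)/Σ(bx²/sy²)` with
`se = 1/sqrt(Σ bx²/sy²)`; MR-Egger as a weighted regression with intercept
after orienting every exposure beta nonnegative, t-distributed tests with
n−2 df. A screen passes when the Egger intercept p exceeds 1e-4, the IVW,
Egger and median-Wald estimates agree in sign (the concordance rule is sign
agreement; no numeric band is externally fixed), and the
Benjamini–Hochberg q is below 5%. Instruments come in four tiers —
sentinels; lead credible-set variants; leads from groups classed specific
or pathway; additionally requiring phenotypic (ontology) specificity — and
reported effects take the most stringent tier that passes
(tier4 ⊆ tier3 ⊆ tier2 by construction).

Convergent trait–disease pairs have at least one passing level effect and
one locus effect from a group not classed disproportional/nonspecific. The
LDL-independence flag requires that no variant at the locus reaches
p < 2.0e-10 on LDL cholesterol *and* no variant's |LDL effect| reaches the
80th percentile of the locus's effect distribution; the sentence defining
the percentile rule admits a laxer either/or reading, which is implemented
behind `rank_rule="or"`.

## Validation experiments and their scope

`metabogen.experiments` plants truth and scores recovery end to end:
credible-set coverage (300 single-causal replicates, n = 50,000, β = 0.15,
MAF 0.2, 50-variant blocks), coloc PP4/PP3 recovery (100 replicates each on
non-overlapping cohort halves), per-mode pleiotropy recovery (250 planted
groups), IVW bias and Egger intercept type-I error (100 / 1,000
summary-level replicates), burden recovery (30 carriers among 20,000) and
PGS-robustness separation (200 genes: shadow signals built by drawing
carriers from a common variant's homozygous background vs genuine
independent effects), effector top-1 recovery on 120 fully informative
synthetic loci against the closest-gene baseline, and Cochran-Q null
calibration (10,000 replicates). Problem sizes are desk-scale choices that
keep the full validation under a few minutes on one core.

Passing these experiments shows the *machinery* is correct and calibrated
under the generator's assumptions — linear additive effects, Gaussian
noise, clean factor structure, LD from a stationary AR(1) process, no
relatedness, no population stratification beyond planted allele-frequency
drift, annotation flags that are perfectly informative. It does not show
that real-cohort effect sizes, LD complexity, assay artifacts or
confounding are handled; in particular the effector classifier's perfect
recovery reflects the fully informative synthetic features, not expected
real-data performance, and the medication correction inherits the
attenuation and confounding structure of real repeat-visit designs only to
the extent the generator models them.

## Known limitations

- Stepwise conditional fine-mapping understates posterior uncertainty when
  several causal variants sit in strong mutual LD.
- Trans-ancestry refinement multiplies ABFs as if ancestries were
  independent samples with shared effects; heterogeneous true effects will
  mis-concentrate the refined set.
- The pleiotropy statistic `statcor` includes the lead trait's own point
  (x = 1 by construction); for groups with few associated traits the
  statistic is biased upward, which is a property of the classification
  rule itself, not of this implementation.
- No X-chromosome dosage handling, no relatedness or mixed models, no
  genomic-control correction, no strand-flip harmonization (synthetic data
  are strand-consistent; real summary statistics would need it).
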