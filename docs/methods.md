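# Methods

`rvburden` implements a rare-variant gene-set burden analysis for small,
extreme-phenotype case/control cohorts sequenced genome-wide — the setting
where a handful of carefully phenotyped subjects at opposite ends of a
disease spectrum (here: schizophrenia versus no psychosis past age 50, in
adults with a 22q11.2 deletion) are contrasted to prioritize biologically
plausible risk mechanisms. This note describes the models, the parameters
that matter, the synthetic data used to exercise them, and the numerical
choices made where the design was open.

## Variant prioritization

A called variant qualifies for the burden analyses when it is:

1. **high quality** — the caller's FILTER field is PASS;
2. **rare** — its alternate-allele frequency is strictly below a threshold
   (default 0.01) in *every* population database in which it was observed.
   A database with no record of the variant imposes no constraint; a
   variant absent everywhere is vacuously rare. This matches standard
   rare-variant practice: the rarity rule is only evaluable on observed
   frequencies.
3. **categorized** into exactly one of three disjoint damage categories:
   - **LoF** — stop-gain/nonsense, frameshift, or core splice site;
   - **damaging missense** — missense with at least `consensus_k` of
     `consensus_n` deleteriousness tool calls positive (default 5 of 7; the
     tools themselves are consumed as annotation columns, not run here);
   - **splicing regulatory** — predicted exon-inclusion change at or below
     a negative cutoff (default −5 percent-units). The underlying splicing
     predictor is a published deep model whose per-variant score is
     consumed as input.

   When a variant satisfies several rules the most severe category wins
   (LoF > damaging missense > splicing regulatory). Most-severe-first is
   the conventional resolution; note this means an exonic missense variant
   that also scores poorly on splicing is counted as missense.

Qualifying variants in the intact 22q11.2 interval and on chromosome X are
*a priori* excluded from the burden tests and reported as separate
per-subject tallies. The excluded interval is a configuration input (BED);
the shipped default is chr22:18,900,000–21,500,000 (hg19, the typical
deletion span), because the study design states the exclusion rule but not
its coordinates. Internally all coordinates are 0-based half-open; VCF
(1-based) and BED (0-based) conventions are converted only at the readers,
and the overlap rule (a VCF position p overlaps [s, e) iff s < p ≤ e) is
property-tested at the boundaries.

Zygosity is ignored in counting: a homozygous variant counts once. Under a
haploinsufficiency model the unit of interest is the damaged gene copy
event, and the reference counts are per-variant, not per-allele.

## Gene-set burden model

For subject *i*, gene set *G*, and category *c*, the burden is the count
k_ic of retained category-*c* variants annotated to at least one gene of
*G* (a variant annotated to two genes of the same set counts once). Before
testing, burdens are percent-normalised:

    b_ic = 100 · k_ic / K_ic

where K_ic is the subject's genome-wide count of all rare, high-quality
variants of that category's *broad class* — all missense variants for the
damaging-missense category (damaging or not), all LoF variants, all
splicing-regulatory variants. This corrects for between-subject differences
in overall variant load. A missense variant that ends up categorized as
splicing-regulatory contributes to both the missense and splicing
denominators, so every in-set count is bounded by its own denominator.

Group comparison is a one-sided two-sample t test (alternative: case mean
greater), pooled-variance Student by default; Welch is available by flag.
Pooled is the classical default and makes the one-variable reduction of the
joint test exact. Degenerate inputs (zero pooled variance) return p = 0.5
at equal means and p → 0 or 1 by the sign of the difference, flagged.

**Screening and joint test.** Gene sets nominally significant for at least
one category (strict p < 0.05 for damaging missense, p < 0.10 for LoF and
splicing regulatory) proceed to a joint test of the three per-subject
category burdens with a two-sample Hotelling T²:

    T² = (n₁n₂/(n₁+n₂)) · d' S⁻¹ d,
    F  = ((n₁+n₂−p−1)/(p(n₁+n₂−2))) · T²  ~  F(p, n₁+n₂−p−1)

with d the mean-difference vector and S the pooled covariance. The joint
test runs on the percent-normalised vectors by default, consistent with
the univariate tests' scale (raw-count mode by flag; which scale the
original analysis used is not stated, so both are exposed). A
zero-variance or rank-deficient category makes S singular; the default is
an error naming the offending variable indices, and a `drop_degenerate`
flag instead removes those categories and lowers the dimension. A silent
pseudo-inverse is deliberately not offered — it would change the null
distribution. At the orchestration level a singular set is recorded as
skipped (with the guidance message) rather than aborting the whole run.

**Effect size** is the between-group ratio of mean absolute variant
counts, mean(case)/mean(control), reported as "nc" (not calculable) when
the control group carries no variants. Displayed group means are raw count
means even though the tests run on percents, matching the convention of
the reference table. No multiple-testing correction is applied; every
p-value is labelled nominal in the output.

**DGCR8 restriction.** Each gene set can be re-tested after intersection
with a configured list of genes predicted to be dysregulated by DGCR8
haploinsufficiency (the miRNA-biogenesis gene inside the 22q11.2
deletion). An empty intersection yields no restricted twin rather than an
empty set.

Display rounding follows the reference table: 2 decimals for means and
ratios, 3 for p-values.

## Power projection

Effect sizes are expressed as Cohen's d (mean difference over the
df-weighted pooled SD, sign convention case − control). Power for a
two-sample pooled t test is computed exactly through the noncentral t
distribution: noncentrality δ = d·√(n₁n₂/(n₁+n₂)), power = P(T′ > t_crit)
with df = n₁+n₂−2, both tails for the two-sided variant. Defaults are
α = 0.05, one-sided, matching the burden tests' sidedness; the published
power bounds (>0.99 at d = 1.90, >0.94 at d = 0.55, N = 100/group) hold
under both sidedness choices, so the unstated original convention is
immaterial to reproduction. scipy's noncentral-t tail occasionally returns
NaN at extreme noncentrality; the implementation detects this and
substitutes the limiting 0/1 mass, and a vectorised Monte-Carlo simulator
(`simulate_power`) provides an independent check used by the tests. A
normal approximation is included for cross-checking only.

## Polygenic risk score

Risk SNPs (with published effect alleles, odds ratios, and association
p-values) are matched per subject either to a variant call — coordinates
and alleles must both agree; the effect-allele dosage a ∈ {0,1,2} comes
from the genotype — or to a reference interval (a span confidently called
homozygous reference) by coordinate overlap. A call at the position with
different alleles leaves the SNP unresolved for that subject (logged, not
an error). Only SNPs resolved in **all** subjects are scored; this
"callable in all genomes" rule is the only completeness mechanism — no
imputation, and no strand reconciliation (alleles must match as given).

Resolving a reference-interval match requires knowing the reference base
at the SNP position, which the score table does not carry. `match_panel`
accepts an optional reference-base lookup; without one it assumes the
other (non-effect) allele is the reference base, the usual A1/A2 table
convention. Under that default a homozygous-reference span contributes
dosage 0; with a lookup naming the effect allele as reference it
contributes 2.

The score at an association threshold is S_i = Σ_j a_ij·β_j with
β_j = ln OR_j, summed in sorted SNP-key order so permuting the input
leaves scores bit-identical. Threshold bins are inclusive for the risk
subsets (p ≤ 0.001, ≤ 0.0001, ≤ 0.00001) and strict for the negative
controls (p > 0.5, > 0.9), exactly as printed. Bins are compared with the
one-sided pooled t test, a one-sided Wilcoxon rank-sum (exact enumeration
for combined n ≤ 20 without ties, normal approximation with tie
correction otherwise), and the maximum correctly-predicted percentage: a
sweep over score thresholds (midpoints of adjacent distinct scores plus
the two extremes), reporting the best **balanced** accuracy (mean of
per-group percent correct). Balanced accuracy is consistent with the
published 83%/75% point estimates on a 6+3 cohort, but the original
definition is unstated; overall accuracy is available by flag.

## Noncoding RNA burden

lincRNA burden is counted as *distinct genes hit* per subject — a subject
with several qualifying variants in one gene counts it once — because gene
involvement, not raw variant count, is the reported unit (variant-count
mode by flag). The formal test restricts to the most conserved genes: the
top decile of the catalog's regional conservation score, where the cut is
⌈fraction·N⌉ genes with all ties at the cut value included. When the
catalog carries per-base conservation, an optional nucleotide-level cutoff
additionally filters variant positions; the two levels are independently
switchable because the original prioritization recipe states both levels
without the combination rule. The percentile is taken catalog-wide (the
score column's provenance is the catalog file's concern).

miRNA genes are short and rarely hit, so their variants are tallied under
a broadened rarity threshold (<5%) and tested only when both groups have a
nonzero subject and the cohort-wide count reaches a minimum (default 5);
otherwise a "tally-only" decision is emitted rather than an uninformative
test.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes; it
is the test bed for every stage and makes no attempt at sequence realism.
Defaults are fixed at the study conditions:

| parameter | default | source / rationale |
|---|---|---|
| n_case / n_control | 6 / 3 | study cohort size |
| lof_rate | 13.8 /subject | reported genome-wide mean |
| missense_rate | 94.3 /subject | reported genome-wide mean |
| splice_rate | 10.0 /subject | not reported; chosen between the LoF and missense loads, consistent with the sparse splicing counts in the reference table |
| damaging_fraction | 0.3 | share of rare missense passing 5-of-7; not reported, consistent with in-set damaging counts of ~5 against ~16 total in-set missense |
| in-set base rates | 0.33 / 5.0 / 1.0 | control-group per-subject means of the ~50-gene neurofunctional set rows |
| lincrna_hit_rates | (2.0, 1.3) | reported mean lincRNA genes hit per subject |
| conservation | Beta(2, 5) | right-skewed scores on [0, 1], typical of conservation summaries |

Counts are Poisson (the minimal assumption given only means are known); a
negative-binomial option with configurable dispersion is available. Per
subject, each broad class total is background + in-set, so totals always
recount exactly. Within a gene set carrying a case:control rate ratio r,
case in-set counts are drawn at base·r and controls at base; under the
null (r = 1) class totals have exactly the configured means. Variants are
materialized on a toy genome (autosomal contig, a PRS contig, an ncRNA
contig, a chr22 with the designated excluded interval, and a chrX) with
unique keys, annotation rows consistent with their intended category, and
sub-threshold allele frequencies. The PRS panel draws Hardy–Weinberg
genotypes; causal SNPs get assoc_p ≤ 0.001, positive log odds ratios, and
an effect-allele frequency shifted by `prs_freq_shift` in cases, while
non-causal SNPs get uniform assoc_p — so the negative-control bins are
null by construction. A fixed seed yields byte-identical output files.

What the generator does **not** emulate: linkage disequilibrium, shared
variants between subjects (rare variants are private), realistic gene
lengths or overlap between gene sets, annotation error, or platform
quality structure. Passing tests therefore demonstrate the correctness and
calibration of the statistics under the assumed sampling model, not
robustness to real-data artefacts.

A deterministic worked example (`generate_worked_example`) encodes
per-subject counts whose group means reproduce the published
ratio-of-means column (1.80; 4.00 after DGCR8 restriction; 2.50; 1.27; and
an "nc" row) together with the reported excluded-variant tallies (3 in the
22q11.2 interval, 8 on X, one of them LoF).

## Problem sizes used in the checks

The bundled checks run at desk scale: type-I calibration uses 1000
replicates of a 50+50 cohort at the count level; effect-ratio recovery 200
replicates at 100/group for ratios 1.5, 2 and 4; power confirmation 10⁴
Monte-Carlo replicates; the PRS calibration 200 replicates of a 25+25
cohort with a 180-SNP panel; generator-mean validation 10⁴ subjects. These
sizes keep the whole suite to a few minutes while leaving Monte-Carlo
error comfortably inside the asserted bands.

## Known limitations

- Headline inferential results of the original study (the joint-test
  p = 0.02, the conserved-lincRNA p = 0.039, PRS group means) depend on
  the nine subject genomes, which are not public; they are covered by the
  calibration and property checks above, not by numerical reproduction.
- The t tests assume approximate normality of percent burdens; at n = 6
  vs 3 this is an approximation the original design also accepts.
- Gene symbols are opaque upper-case strings; no alias resolution.
- No de novo/inherited distinction (no parental genomes), no CNV/SV
  handling, no LD clumping of the PRS panel, and no re-annotation or
  liftover — annotations and SNP weights are consumed as published.
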