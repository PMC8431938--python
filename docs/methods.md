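# Methods

## Model and procedure

The pipeline treats a tumor cohort as a collection of samples with matched
tumor/normal DNA calls, tumor RNA allelic counts, and a normalized
expression matrix. Its object of study is the set of non-cancer pathogenic
or likely pathogenic germline variants (NC P/LPs): classification labels
(ACMG five-tier) arrive as input annotations; the pipeline does not score
pathogenicity itself.

### Read-support filtering

A carrier call survives when it has at least `min_alt` (default 5)
alternate reads **and** variant allele fraction at least `min_vaf` (default
0.2) in both the tumor and the normal data; both thresholds are inclusive,
and zero depth in either tissue rejects the call. The rationale is
symmetric germline evidence: a true heterozygous germline variant should
show balanced support in both tissues. The recall path for the 34
non-cancer ACMG secondary-findings genes requires only alt ≥ 5 in either
tissue, without the VAF clause — these genes are medically actionable, so
recall is favored over precision there; the two retained sets are unioned
and de-duplicated by (sample, variant).

### Non-cancer triage

A variant is cancer-related when its gene is on the configurable
152-gene cancer-predisposition list (shipped default in
`src/germex/data/cancer_genes.txt`), or any ClinVar trait string contains
"tumor", "cancer" or "neoplasia" (case-insensitive substring), or any
alphabetic trait token ends in "-oma" (a trailing plural "s" is stripped
first) and is not on the benign exception list (glaucoma, hematoma,
xanthoma, coloboma, …). Suffix matching with an editable exception list was
chosen because "-oma" overwhelmingly denotes neoplasms but has a short,
enumerable list of benign exceptions; both lists are plain text files the
user can replace.

### Carrier frequencies

Carrier metrics are person-level: a sample carrying several NC P/LPs (or a
homozygous genotype) counts once. Frequencies divide by the ancestry-group
size; percentages are displayed half-up rounded to 2 decimals while raw
counts are always retained so any other rounding can be recomputed.
Population exclusivity requires *all* carriers of a variant in one
ancestry; carriers of mixed/other ancestry disqualify the flag (admixture
makes exclusivity unsafe), and groups under 100 samples are not reported
(configurable).

### Reference-population comparison

For each variant and matched reference population the 2×2 table is
`[[cohort_AC, cohort_AN − cohort_AC], [ref_AC, ref_AN − ref_AC]]` with
cohort AN = 2 × group size — an autosomal-diploid convention (heterozygous
carriers contribute one allele, homozygous two); sex chromosomes are out of
scope. European cohort samples compare against the pooled NFE + FIN
reference alleles. Fisher p-values are BH-adjusted within each population;
the per-population Pearson correlation uses allele frequencies of variants
present in both tables.

### Expression impact

The dependent variable is the within-gene, within-cancer-type ecdf
percentile (fraction of stratum values ≤ own value, self-inclusive, ties
shared), which makes the analysis invariant to monotone normalization of
the expression matrix. Per gene with ≥ 3 carriers, OLS regresses the
percentile on a carrier indicator (1 if the sample carries *any* NC P/LP in
the gene — variants pool per gene) plus age, a male indicator (female
reference), tumor purity, PC1, PC2, and cancer-type one-hots with the
lexicographically first type as reference (deterministic choice). BH runs
across tested genes; tiers are FDR < 0.05 (significant) and 0.05 ≤ FDR <
0.15 (suggestive). Exactly collinear designs are skipped with a log entry
rather than failing the run. The bottom-quartile co-occurrence view uses an
inclusive boundary (percentile ≤ 0.25 counts).

### Allele-specific expression

Only heterozygous carriers are tested (allelic imbalance is undefined for
homozygotes). The rarity filter keeps population AF ≤ 0.05%; a missing AF
passes with a warning, since annotation gaps should not silently remove
records. Per carrier-variant the single RNA source with the greatest depth
at the allele is kept (ties broken by smallest source id for determinism),
then depth ≥ 6 is required. The test is the exact lower-tail binomial
P[X ≤ alt] under Binomial(ref+alt, 0.5); BH runs over all tested records
pooled — a single adjustment before any gene grouping. Gene enrichment
requires ≥ 3 significant records and a significant fraction strictly above
70%, then applies a two-sided Fisher test on in-gene × significant counts
over all tested records (a flag switches the counting unit to unique
variants). Class enrichment permutes the significant/not labels across all
records with class sizes fixed; p is the fraction of shuffles whose class
proportion strictly exceeds the observed one (an optional (b+1)/(B+1)
smoothing flag exists, off by default, so a reported 0 means "never
exceeded in B shuffles").

### Mis-splicing

Per assay the allelic ratio is log2((alt+ps)/(ref+ps)) with pseudocount
0.5 (Haldane–Anscombe-style zero guard, configurable); negative means the
alternate allele is depleted among correctly spliced species. The assay
itself does not define a significance test here, so the exact two-sided
binomial test vs 0.5 — min(1, 2·min(lower, upper tail)) — is used,
consistent with the count nature of the data and the package's exact
kernel; this convention is recorded in the run manifest. BH runs within
each assay across variants. A variant is called mis-splicing only when FDR
< 0.05 and ratio < −log2(1.5) ≈ −0.585 hold in **both** assays; a variant
missing one assay is called negative and flagged incomplete. Cohort
matching is an exact (chrom, pos, ref, alt) join and refuses mismatched
genome-build tags outright — no coordinate liftover is attempted.
Input-plasmid normalization of assay ratios is out of scope.

## Statistical kernel

`stats_core` computes binomial and hypergeometric probabilities exactly by
summing terms in log space (`lgamma`-based), so p-values remain accurate at
RNA depths of 10⁴ and beyond; no normal approximation is used. The
two-sided Fisher p sums all tables with the observed margins whose
probability is ≤ the observed table's probability within a relative
tolerance of 1e-7 — the convention of mainstream implementations, recorded
in output metadata since other two-sided definitions exist. BH is the
classic step-up with stable sorting, so tied p-values share an adjusted
value. OLS uses least squares with n−k residual degrees of freedom and
t-distribution p-values; a zero-residual-variance fit returns NaN p-values
with a flag instead of raising, because exactly collinear synthetic
fixtures are legitimate inputs. Degenerate Pearson inputs (zero variance,
n < 3) raise.

## Synthetic data

The generator's defaults emulate the cohort structure this pipeline is
designed around: 10,389 samples in the ancestry mix 8,279 EUR / 971 AFR /
652 EAS / 305 Latinx / 50 SAS / 106 mixed / 26 other; per-ancestry carrier
rates near the observed frequencies (EUR 0.2675, AFR 0.1298, EAS 0.1166,
Latinx 0.1508); age ~ Normal(60, 10) truncated to 20–90; purity ~
Beta(5, 2); PCs ~ Normal(0, 1). Read depths are negative-binomial (DNA
mean 60, RNA mean 40, dispersion 5) rather than fixed so that the ≥ 5 /
≥ 6 read thresholds are genuinely exercised; allele counts are binomial at
0.5 for heterozygotes. Planted effects: ASE variants draw RNA alternate
reads at fraction 0.1; expression-lowering genes re-center carrier values
at 0.5 − shift (default shift 0.3) plus Normal(0, 0.1) noise on a latent
uniform scale, so the pooled-stratum ecdf recovers the planted percentile
shift with negligible attenuation; mis-splicing variants split assay reads
1:3 at depth 300. The generator does **not** emulate linkage structure,
mapping bias, tumor copy-number distortion of allelic ratios, batch
effects, or covariate-correlated expression — passing tests therefore
demonstrate correctness of the statistical machinery under the stated
sampling model, not robustness to those real-data artifacts.

Headline fixtures are deterministic constructions whose summary statistics
equal specific printed counts exactly (e.g. 2,505 carriers of 10,389
samples; 173 of 657 ASE records significant, planted at alt = 0 of 30 so
significance survives BH regardless of the rest of the fixture, with 28
suggestive records at alt = 9 of 30 whose shared BH value lands in
[0.05, 0.15)). They exist so worked-example tests are exact rather than
stochastic.

## Problem sizes and determinism

The test suite uses scaled-down cohorts (400–10,000 samples, 120–400
variants) chosen so each statistical property is measurable with margin:
1,000 records for ASE calibration/power, 100 replicates × 3 shifts for
expression recovery, 500 replicates for the splicing classifier, exhaustive
enumeration to grand total 40 (Fisher) and n = 60 (binomial) for the
kernel. All randomness flows through `numpy.random.default_rng` seeds;
permutation tests and the CLI are single-threaded by contract, and two runs
with identical inputs and seeds produce byte-identical outputs.

## Known limitations

Classification labels, inheritance modes and population AFs are trusted
inputs. Indel keys must match exactly (no normalization or liftover). The
expression model assumes percentiles respond linearly to covariates, which
is a pragmatic approximation on a bounded scale. ASE uses tumor RNA, where
copy-number alterations can mimic allelic imbalance; no correction is
attempted. The shipped cancer-gene list is an editable default, not a
canonical registry.
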