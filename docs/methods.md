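# Methods

## The scan statistic

Every unordered pair of distinct SNPs is tested with the four-parameter
linear model y = β₀ + β₁g₁ + β₂g₂ + β_int·g₁g₂ + ε on the covariate-adjusted
phenotype residual. The reported statistic is t = β_int/SE with df = n − 4
(intercept, two marginals, the product term); at n = 2996 the |t| = 5
emission threshold corresponds to a two-sided p of 6.06·10⁻⁷. The engine
assembles each pair's 4×4 normal equations from cross-product sums computed
once per SNP chunk, so the cost per pair is a batched 4×4 solve rather than
an O(n) regression; an oracle test pins the result against naive per-pair
OLS to 10⁻⁸ relative, and a chunking test verifies the output is identical
for chunk sizes 2, 7 and 1000.

Covariates never enter the scan itself: the phenotype is residualised on
intercept + sex + age first (exact OLS projection), after excluding
lipid-lowering-medication users. Because the t-statistic of an OLS
coefficient is invariant under affine transforms of the response, the
standardised residual used for discovery and the raw-scale residual used
for replication give identical t and p; only β_int changes scale (by the
residual SD). Standardisation uses the population SD (denominator n) — the
choice is arbitrary under that invariance and is fixed for reproducibility.

Degenerate pairs are skipped, not emitted: a product column whose variance
falls below a guard (default 10⁻¹²), or a normal matrix with condition
number above 10¹² (e.g. a SNP paired with an LD-perfect copy of itself).
At low MAF and moderate n a pair can be *fully* degenerate — no individual
carries minor alleles at both SNPs, so the product column is identically
zero and the interaction is simply not estimable in that sample. These are
tallied in the log.

## Quality control

Per-SNP exclusion rules, applied in fixed order so each exclusion names one
rule: MAF < 0.05 (computed on the pooled discovery + filter samples when
cohorts share a SNP panel, else per cohort), call rate < 0.95, and
Hardy–Weinberg exact-test p < 10⁻⁷. The HWE test is the exact conditional
test: given the allele counts, it sums the probabilities of all
heterozygote configurations no more probable than the observed one (plain
exact, no mid-p correction). A chi-square test would be unreliable at the
10⁻⁷ tail that the QC rule uses; the exact test is computed with log-gamma
arithmetic and checked against an exact-fraction enumeration oracle.
Exact-test p-values are discrete — there is an atom at p = 1 for the
conditional mode — so calibration checks against the uniform distribution
are only meaningful at sample sizes large enough for the lattice to be
fine (the generator test uses 5000 individuals per SNP).

Missing genotypes: the scan's closed-form cross-products require a complete
matrix, so missing calls are mean-imputed per SNP (rounded to the nearest
legal genotype) after QC, with the imputed fraction logged. The call-rate
rule bounds the imputed fraction at 5% per SNP.

## Meta-analysis, filtering, pruning

Per-cohort refits of candidate pairs are pooled with inverse-variance
fixed-effects weights; the pooled p is the two-sided normal tail of
|β̂/SE| (cohort df are large; a t reference would change nothing at the
thresholds involved). Cohorts in which a SNP is absent are *untestable*,
not errors: they are skipped in the pooling and recorded as '?' in the
per-cohort direction string. Candidate filtering keeps pooled p strictly
below 10⁻⁸.

Two interaction terms are redundant when their SNPs can be matched across
terms — in either assignment — with both matched genotype r² above 0.8.
LD here is the squared Pearson correlation of 0/1/2 counts (composite r²):
phase is unavailable in this data model, and count correlation is the
standard unphased surrogate. Pruning is greedy in ascending pooled-p
order, so each redundancy class keeps its most significant member; the
kept count m sets the replication threshold 0.05/m (with m = 132 this is
3.79·10⁻⁴). The matching rule is the weakest one that makes whole-term
collapsing well defined; it is configurable, and the pruning report lists
every removed term with its retained representative.

## Replication and the medication check

Replication refits each kept term per held-out cohort on the *unscaled*
adjusted phenotype (so β_int is in phenotype units and comparable across
cohorts), pools over replication cohorts only — discovery cohorts never
enter the pool, which a construction-audit test asserts — and calls a term
replicated at pooled p < 0.05/m, nominal at p < 0.05, both strict. A
cohort can be flagged to keep medication users (some studies do not record
or exclude them); the flag is honored per cohort.

The medication case-control model is
logit P(user) = β₀ + β₁g₁ + β₂g₂ + β_int·g₁g₂, with cases = medication
users with phenotype available and controls = the (unmedicated) analysis
sample; the combined fit pools raw individuals across cohorts with k − 1
cohort-membership indicator columns. The combined estimate is deliberately
*not* the inverse-variance meta of the per-cohort fits — the two are
distinct estimators that agree only asymptotically, and the tests compute
both on one dataset to keep the distinction honest. The fit is Newton
scoring (IRLS), max 100 iterations, convergence when the largest
coefficient step is below 10⁻¹⁰, Wald SEs from the inverse information;
perfect separation raises an explicit error rather than returning a
diverged fit. Cross-checks: a derivative-free likelihood maximiser and
statsmodels on the same data.

Directional triage of a term uses three signs: discovery HDL effect,
replication HDL effect, medication effect. Discovery/replication
disagreement ⇒ *sign-discordant* (probable false positive); same HDL and
medication signs ⇒ *counterintuitive* (an allele combination that raises
HDL should not raise treatment odds); otherwise *consistent*. The full
8-row truth table is tested.

## Power analysis

For a single tested coefficient with standardised effect f (Cohen's f; the
test's noncentrality is δ = f·√n), power is the noncentral-t tail beyond
the central-t critical value at df = n − df_model − 1, df_model = 3 by
default to match the scan. The smallest detectable effect inverts this by
Brent root-finding on [0, 10] to 10⁻¹⁰. One-tailed α is the default: with
n = 2996 and α = 10⁻⁷ it reproduces 0.11 / 0.095 / 0.05 at 80% / 50% / 1%
power, whereas a two-tailed convention would give ≈ 0.113 / 0.098 / 0.053;
`tails` is an explicit parameter. At f = 0 the computed power equals α
(the test's size), and the round trip effect → power → effect closes to
10⁻⁶.

## The synthetic-cohort generator

The generator emulates the structure the analysis assumes, not human
genetics in detail. Genotypes are two independent Bernoulli allele draws
per individual (Hardy–Weinberg), MAF uniform on a configurable interval
(default 0.05–0.5, matching the QC floor). LD blocks copy a founder SNP's
alleles with a per-allele flip probability solved numerically from the
target genotype r² — controllable, and oracle-checkable with a sample
correlation; it does not mimic real haplotype maps, recombination or
imputation uncertainty. The phenotype is
intercept + sex·β_sex + age·β_age + Σ marginal + Σ β_int·g₁g₂ + N(0, σ):
defaults (intercept 1.2 mmol/L, sex effect 0.25, age effect 0.002/yr, age
uniform on 55–80 echoing a 55+ recruitment design, noise SD 0.35) give an
HDL-like trait with mean ≈ 1.5 and SD ≈ 0.42 mmol/L. Medication use is
Bernoulli(logistic(1.0 − 2.0·HDL)), i.e. lower HDL raises treatment odds,
giving ≈ 12–15% users; an optional direct g₁g₂ term in the treatment
process lets tests plant a medication signal. One spec can emit several
cohorts with identical effects but independent draws (seeds spawned
deterministically from the master seed), and a replication-effect scale of
0 produces pure-null replication cohorts for calibration studies. Equal
seeds give bit-identical files.

Consequently, passing tests show that the pipeline recovers planted
effects of known size under its own model assumptions and that its error
rates are calibrated under that model; they say nothing about confounding,
population structure, genotyping artefacts or phenotype measurement error
in real cohorts.

## Problem sizes and numerical choices

The bundled study (analysis drivers, end-to-end tests) uses 6 cohorts of
700–1500 individuals × 30 SNPs with one planted 0.45 mmol/L interaction —
large enough that every stage has genuine work (435 pairs, an LD duplicate
to prune, three-cohort pooling) and small enough that the whole flow runs
in seconds; calibration tests use up to 200 SNPs × 2000 individuals
(19,900 pairs). Output ordering is everywhere deterministic (descending
|t|, then lexicographic names); the p < 10⁻⁸ filter and both replication
flags use strict inequalities; Bonferroni α·m = 0.05 exactly by
construction. The pipeline summary records each stage's threshold and
count, with the proposed GWIS-wide significance level 10⁻¹³ printed as a
reference line — the study design's central bookkeeping lesson.

## Known limitations

- No covariates inside the scan (residualise first); no mixed models for
  relatedness; no principal-component adjustment.
- No dosage/imputation-uncertainty support; genotypes are hard 0/1/2 calls.
- Fixed-effects meta only; no heterogeneity statistics.
- The pair-redundancy rule for pruning is a declared convention; other
  reasonable rules (single-SNP overlap, haplotype r²) would give different
  m.
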