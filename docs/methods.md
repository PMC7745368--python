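# Methods

`chbgrs` implements the statistical machinery of a candidate-gene
case–control study of chronic hepatitis B (CHB): per-SNP association tests,
linkage-disequilibrium (LD) screening for signal independence, and a
cumulative genetic risk score (GRS) over 11 susceptibility loci. This note
documents the models, conventions and design choices; every number quoted
here is computed by the package's tests or acceptance script.

## Data model

Genotypes are stored as an individuals × SNPs matrix of minor-allele
dosages (0/1/2; `nan` marks a failed call). The minor allele is determined
**once in the pooled sample** (cases and controls together) and never
re-determined per subgroup, so a subgroup frequency may exceed 0.5. Loaders
(TSV and VCF v4.2) re-orient any column whose counted-allele frequency
exceeds 0.5; the operation is involution-safe. All statistics are
complete-case per marker: an individual missing at one SNP still
contributes to every other SNP.

Published tables report genotype *counts* per group, not individuals.
`expand_counts` converts a count table into an individual-level dataset by
a fixed per-SNP expansion order (dosage 0 block, then 1, then 2, remainder
missing), which makes the expansion deterministic and exactly invertible by
`counts_from_dataset`. Because only marginals are published, the joint
genotype structure of the expanded cohort is an artifact of that ordering:
single-SNP statistics on the fixture are exact, whereas any cross-locus
quantity (conditional regression estimates, joint GRS bin counts) is not a
reproduction of the study's unpublished individual-level data. The built-in
fixture covers 955 cases and 761 population controls at 11 loci; per-SNP
count shortfalls against the group sizes (e.g. 923 of 955 cases genotyped
at rs12614) are modelled as assay failures, i.e. missing. SNP positions are
ordinal placeholders (the source tables print none); no analysis uses
position.

## Association tests

**Allele test.** For each SNP the 2×2 table of minor/major allele counts in
cases and controls gives the cross-product odds ratio
OR = (a·d)/(b·c), a Woolf confidence interval
exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d)), and a 1-df Pearson chi-square
P (no Yates correction). A zero cell triggers the Haldane–Anscombe
correction (+0.5 to all four cells) for the OR and CI; a zero margin is an
error.

**Display convention.** Report tables truncate ORs and CI bounds toward
zero at two decimals. Truncation, not rounding, is the convention under
which the recomputed values agree digit-for-digit with the published tables
at all 11 loci (e.g. raw 1.6577 → 1.65, raw 0.5399 → 0.53, CI bound 1.9940
→ 1.99); half-away-from-zero rounding would disagree at five of them.
Full-precision companion columns are always emitted alongside.

**HWE.** Hardy–Weinberg equilibrium is tested per group by a 1-df
chi-square against expected counts from the observed allele frequency, or
by the exact test conditional on allele counts (Wigginton-style: sum the
probabilities of all heterozygote configurations no more likely than the
observed one). Whether HWE should be assessed in controls only or in all
subjects is a study-design question the source leaves open; the pipeline
reports both. Monomorphic SNPs return P = 1 with a warning.

**Logistic models.** The additive model regresses case status on dosage
(0/1/2), optionally adjusting for age (years, continuous) and sex
(0 = male, 1 = female), and reports the per-allele OR exp(β) with Wald CI
and P. The fitter is an in-package IRLS Newton solver: convergence when the
largest coefficient change falls below 1e-8 (cap 100 iterations), standard
errors from the inverse observed information. Perfect separation is
detected as any |β| > 15 and flagged rather than raised, so small simulated
datasets cannot crash a run. A singular information matrix raises, except
in the conditional-analysis path, where it is flagged `collinear` and the
target's result is reported as null (OR 1, P 1) — the behaviour wanted when
a conditioning marker is a perfect proxy (r² = 1) of the target.
Conditional analysis adds a known marker's dosage to the model and reads
the target's coefficient; it quantifies whether a signal is independent of
previously established loci. Bonferroni correction uses m = 40 by default
(10 SNPs × 4 group comparisons, the burden implied by the published
corrected P values); m is a configuration knob.

The published per-SNP ORs were covariate-adjusted, but individual ages and
sexes were never released, so the package cannot reproduce them exactly
from counts. Tests therefore assert procedure properties instead: the
unadjusted additive OR for rs12614 on the count-expanded cohort lies in
[0.40, 0.48] (bracketing the published adjusted 0.43), IRLS equals the
closed-form 2×2 logistic solution, and simulated per-allele log-ORs are
recovered with |bias| < 0.05 at n = 10 000 over 100 seeds.

**Split validation.** Repeated case/control-stratified random splits run
the association independently on training and test halves; effect-direction
concordance is the summary. Splits are reproducible given a seed; degenerate
splits are skipped with a warning.

## Linkage disequilibrium

Two-locus haplotype frequencies are estimated from unphased genotypes by
EM: every genotype except the double heterozygote has a determined gamete
composition; the double heterozygote splits between the coupling (AB/ab)
and repulsion (Ab/aB) phases in proportion to f_AB·f_ab vs f_Ab·f_aB.
Initialisation is at linkage equilibrium (product frequencies), convergence
when the largest frequency change falls below 1e-9 (cap 1000 iterations).
The two-locus likelihood is well-behaved in practice; a single start is
used and multi-start is deliberately out of scope. From the fitted
frequencies: D = f_AB − p_A·p_B; |D′| = |D|/D_max with the Lewontin bound
D_max = min(p_A·p_b, p_a·p_B) for D > 0 and min(p_A·p_B, p_a·p_b)
otherwise; r² = D²/(p_A·p_a·p_B·p_b). Values are clamped against
floating-point overshoot; for biallelic loci r² ≤ |D′| ≤ 1 holds and is
property-tested. Pairs are pairwise-complete-case; a pair monomorphic in
the shared subset is flagged degenerate with r² = 0 by convention. |D′| is
reported unsigned. The independence screen reports, for a focal SNP against
a marker list, whether every pairwise r² is at or below a threshold
(default 0.15). Haplotype-block detection and >2-locus inference are
non-goals.

## Genetic risk score

Each SNP's two-decimal allele-test OR defines a per-genotype score table:
1 for the major homozygote, OR for the heterozygote, and for the minor
homozygote 2·OR when OR > 1, OR/2 when OR < 1, and 1 at OR = 1. Scores are
rounded half away from zero to two decimals (0.245 → 0.25, 0.265 → 0.27).
The homozygote rule is adopted from the published per-genotype values
(3.44 = 2 × 1.72 on the risk side but 0.22 = 0.44/2 on the protective
side); a literal doubling on both sides would contradict the published
protective-homozygote scores, and only the adopted rule reproduces the
published cumulative range. The OR = 1 boundary is where the two competing
rules conflict, and the neutral convention (score 1 at every genotype) is
used. An individual's cumulative GRS is the sum of their genotype scores
over the model's loci; under the `skip` missing policy a missing locus
contributes nothing and coverage is recorded. The theoretical range is the
sum of per-SNP minima and maxima; on the 11-locus model recomputed from the
count table it is exactly (5.24, 17.38) — note this requires scoring from
the two-decimal ORs (unrounded ORs would give a minimum of 5.22).

Binned odds ratios compare each GRS interval with a reference bin via the
2×2 cross-product with Woolf CI (continuity-corrected on zero cells) and
are reported on the log10 scale. Default bins follow the published figure's
anatomy: open ends below 7 and above 14, reference interval [9.8, 11.2),
intermediate bins of width 1.4; fully overridable. The published per-bin
ORs (0.17 below 7; 3.42 above 14) depend on the unpublished joint genotype
distribution and are therefore checked only as a property — log-odds linear
in GRS must give monotone binned log-ORs — on simulated data. The
case-vs-control GRS comparison defaults to the two-sided Wilcoxon rank-sum
test (the distribution's shape is unknown; the source does not name its
test); Welch's t is selectable. Fully tied data report P = 1. A
conventional variance-weighted log-additive polygenic score is a
documented future extension, not part of this scheme.

## Synthetic cohorts

`simulate_cohort` draws genotypes at Hardy–Weinberg proportions per SNP
(haplotype-level coupling for pairs with a target r², solved from
D = √(r²·p₁q₁·p₂q₂) and checked against the exact feasibility bound),
assigns disease by a logistic model with per-allele log-odds ln(OR) per
locus, and then samples the requested numbers of cases and controls from
the population pool — outcome-dependent sampling, under which the
per-allele odds ratio remains the recoverable quantity. The intercept
centres the linear predictor so both outcomes are plentiful in the pool;
this choice affects efficiency only, not the ORs. Defaults mirror the study
conditions: 955 cases vs 761 controls, the 11 loci's pooled minor-allele
frequencies and two-decimal allele-test ORs. Ages are normal
(mean 50, SD 10 in both groups) and sex Bernoulli (female fraction 0.3 in
cases, 0.5 in controls); these covariate defaults are generic cohort values
chosen once, since the study's subject-characteristics table is not
reproduced here, and they matter only for exercising the adjustment code
path. Missingness is applied uniformly at random per SNP, last. LD targets
must form disjoint locus pairs.

What the simulator does **not** emulate: population structure and ancestry,
genotyping batch effects, departures from HWE in controls,
covariate–genotype correlation, and LD beyond pairwise coupling. Passing
calibration tests on these cohorts therefore demonstrates correctness of
the estimators under the stated model, not robustness to real-data
artifacts.

## Problem sizes and numerical choices

Test simulations use n = 1000/1000 (type-I-error calibration, 500
replicates), n = 5000/5000 × 100 seeds (effect-recovery bias), and n = 2000
haplotype draws (EM recovery within 0.02); these sizes give the stated
tolerances comfortable headroom while keeping the suite fast. P values are
floored at the smallest positive double and capped at 1. Two-decimal
display goes through a fixed-point string so binary-float dust cannot flip
the last digit. Ties in the minor-allele determination (frequency exactly
0.5) keep the file's orientation.

## Known limitations

- Conditional-analysis output on the count-expanded fixture reflects the
  arbitrary joint structure of the expansion, not biology; it is provided
  because the pipeline runs end-to-end, and is meaningful only on true
  individual-level data.
- The allele-test P uses the Pearson chi-square; the published allele-test
  P values appear to derive from a slightly different statistic and agree
  only to within ~20% in the far tail (ORs and CIs agree exactly).
- No genomic control, mixed models, ancestry adjustment, imputation,
  phasing, or multi-allelic support.
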