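# Methods

## Study design the package models

A candidate gene (POMC, four exons) is Sanger-resequenced in a two-population
case-control sample: African American (AA) and European American (EA)
subjects, where cases carry a DSM-IV lifetime diagnosis of substance
dependence (alcohol, cocaine, opioid and/or marijuana — SD = the OR of the
four) and controls are screened negative for all four. Population membership
is assigned from a model-based African-ancestry proportion: ≥ 0.50 → AA,
otherwise EA (ties go to AA by the stated rule); the same proportion also
enters regressions as a continuous covariate. BMI is categorised by the WHO
cut points as half-open intervals — underweight < 18.5, normal [18.5, 25),
overweight [25, 30), obese ≥ 30 kg/m²; the conventional "24.9"/"29.9" upper
bounds are display forms of the same cuts. Subjects who are neither cases
nor screened controls are retained but excluded from case-control contrasts.

Every allele count is an `n/N` pair. Because the four exons amplify with
different success rates, N varies site by site — within exon 4 alone the
packaged table has three distinct denominator blocks, so the effective
sampling unit is the amplicon, not the exon. Subjects failing sequencing at
a site are dropped per-site, never listwise. The minor allele is oriented by
the pooled control sample; for the 9-bp indel the insertion allele is minor.

## Common-variant tests

- **Allelic 2×2 χ²**: Pearson's statistic n(ad−bc)²/(r₁r₂c₁c₂) without
  Yates correction, 1 df. OR = ad/bc with a 0.5 Haldane–Anscombe increment
  to all cells only when some cell is zero; 95% CI by Woolf's log interval.
- **Permutation empirical p**: group labels are permuted, dosages fixed;
  the estimator is (1 + #{permuted χ² ≥ observed}) / (1 + n_perm), which
  cannot return zero; the default is 10,000 permutations. Deterministic
  under a seed.
- **Logistic regression** (statsmodels ML fit): additive allele coding;
  covariates are sex, age and ancestry proportion, plus BMI when the outcome
  is an SD trait and SD status when the outcome is a BMI contrast. Wald z
  and p are reported. Separation or non-convergence raises an explicit
  error rather than fabricating a p-value. Covariates constant within a
  stratum (e.g. ancestry in a single-population run) are dropped.
- **BMI contrasts**: overweight, obese, and overweight+obese, each against
  normal weight, with cases and controls pooled; the handful of underweight
  subjects sits outside all three.
- **HWE**: the exact test conditions on observed allele counts and sums the
  probabilities of heterozygote configurations no more probable than the
  observed one (Levene/Haldane conditional distribution); a 1-df Pearson
  goodness-of-fit version is available; monomorphic input returns p = 1.

## Two-locus haplotypes

With two biallelic loci only the double heterozygote is phase-ambiguous. EM
starts from linkage-equilibrium frequencies (product of observed allele
frequencies), splits each double heterozygote between cis and trans in
proportion to f(AB)f(ab) vs f(Ab)f(aB), and stops when no frequency moves by
more than 1e-8 (the log-likelihood is asserted non-decreasing at every
step). Allele margins are complete data, so the likelihood has one free
parameter and a single EM start suffices in practice; tests guard this with
an independent zooming grid-search maximiser. LD summaries: D = f(AB) −
p_A p_B, D′ = |D|/D_max with the usual sign-dependent D_max, r² =
D²/(p_A p_a p_B p_b) (undefined when a locus is monomorphic). Haplotype
association fixes the posterior fractional haplotype counts from the
pooled-sample EM, compares each haplotype between strata with a 1-df χ² on
expected counts, permutes stratum labels for the empirical p, and flags
haplotypes with an expected count below 1 in either stratum as unreliable.

## Rare-variant collapsing burden test

Sites are classified rare when the larger of the pooled-case and
pooled-control MAF is strictly below the threshold. The working default is
0.012 rather than the nominal 0.01 so that a site whose MAF rounds to 0.011
at these sample sizes — rare for every practical purpose — stays in the
panel; the nominal cut is one flag away. On the packaged table this yields
the 21-site panel (the two common polymorphisms excluded).

For one analysis group with panel sites i = 1..n, the collapse computes the
harmonic-mean chromosome total N = n/Σ(1/Nᵢ) and the adjusted minor-allele
count Σᵢ pᵢ·N (pᵢ = nᵢ/Nᵢ), rounded half-away-from-zero to an integer since
the exact test needs integer cells; when all Nᵢ are equal this reduces
exactly to the raw sum. Two groups are compared by a two-sided Fisher exact
test on [adj_minor, N − adj_minor] per group, with two-sidedness by the
probability-ordering convention of R's `fisher.test` (all tables with the
observed margins whose probability is within a 1e-7 relative tolerance of
not exceeding the observed table's), computed in log space. Because the
intermediate rounding is a convention rather than data, an unadjusted
sensitivity p on the raw sums over Σᵢ Nᵢ chromosome-site observations is
always reported alongside. Trait-specific case groups (AD/CD/OD/MjD) are
non-exclusive subsets of the SD cases compared against the same screened
controls; Bonferroni correction applies across those five contrasts
(threshold α/5 = 0.01), never inside the collapse.

On the packaged table the collapsed raw numerators are 16 (AA cases), 4 (AA
controls), 14 (EA cases) and 18 (EA controls), and the adjusted counts
coincide with them. The harmonic-mean denominators computed from the table's
own Nᵢ (≈ 280, 211, 261, 308) differ from the denominators printed alongside
those numerators in the source report (265, 208, 248, 290), which are not
reproducible from the published per-site denominators under the stated
formula; this package reports the formula's value, and consequently its
exact p-values (AA SD: 0.038) differ somewhat from the printed ones (0.026).

## Synthetic cohorts

The generator emulates the study conditions; its preset
(`pomc_study_preset`) is fixed at the published design:

- group sizes 167/113 AA cases/controls and 144/164 EA (the 588-subject
  total; the alternative 114 EA-case figure circulating in the source's
  summary is arithmetically inconsistent with its own totals and per-site
  denominators and is recorded but not used);
- the two common sites drawn as two-locus haplotypes under HWE at the
  published control MAFs (insertion 0.284 AA / 0.048 EA; 3′UTR T allele
  0.140 AA / 0.210 EA), with signed D′ = −0.9 (minor alleles in repulsion),
  which reproduces the observed tight-LD / low-r² pattern (simulated draws
  give D′ ≈ 0.85–1.0 with r² ≈ 0.01–0.05);
- rare sites as independent binomial(2, f) draws (no LD among rare sites)
  at the per-population pooled frequencies of the packaged table;
- per-group, per-amplicon dropout probabilities solved from 1 − N/(2n) so
  the expected denominators reproduce the published ones;
- SD from a logistic liability: logit P = β₀ + ln(OR_burden)·(rare alleles
  carried) + 0.2·male + 0.1·(age−40)/10 + 0.3·(ancestry−0.5), with
  age ~ N(40, 10), P(male) = 0.6, ancestry ~ 0.5 + 0.5·Beta(5,2) for AA and
  0.5·Beta(2,5) for EA (arbitrary but fixed); the preset burden OR is 3.3,
  the allele-level enrichment the published collapsed AA counts imply;
- BMI by category: odds of overweight+obese vs normal follow
  ln(OR_bmi)·dosage at the 3′UTR site in EA subjects only (preset OR 2.0,
  matching the published adjusted estimate), baseline logit 0.95,
  underweight probability 0.005, obese share of the high stratum 0.46, and
  BMI values from truncated normals per category using the published
  category means/SDs (22.4±1.6, 27.1±1.4, 35.5±5.1);
- case/control quotas met by rejection resampling from an oversized pool —
  exact under the null, mildly effect-shrinking under strong effects.

What the generator does **not** emulate: LD between rare sites, genotyping
error, relatedness, fine population substructure within AA/EA, shared
genetic control of SD and BMI, or any retrospective-likelihood ascertainment
correction. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not robustness to
those real-data features.

## Numerical choices

- Fisher p-values and hypergeometric weights computed with cached log-gamma
  tables; ties in probability ordering resolved with the 1e-7 relative
  tolerance (R convention), and 1e-12 in the HWE exact test.
- EM tolerance 1e-8 on the max frequency change, cap 10,000 iterations,
  non-convergence reported; frequencies renormalised and clipped at 0.
- Rounding of adjusted counts: half away from zero.
- Bisection for the minimum detectable OR to 1e-4 between 1 and 100; the
  power formula is the Fleiss continuity-corrected two-proportion form
  (the classic PS program's dichotomous default) on allele counts (2 per
  subject), matching the allelic test being powered. Against the published
  retrospective values this reproduces 1.70 vs 1.67, 2.51 vs 2.50, 1.93 vs
  2.00 and 1.71 vs 1.68 — residual differences reflect the unstated variant
  of the correction used originally.
- Degenerate inputs: zero-margin 2×2 tables are rejected in the χ² (no
  information) and return p = 1 in the exact test (single possible table);
  empty groups are flagged degenerate with n/N = 0/0; monomorphic loci make
  LD undefined and are rejected explicitly.

## Test problem sizes

The suite's simulation-based checks use cohorts of 240–300 subjects for
null calibration (500 replicates), n = 4000 for logistic effect recovery
(100 replicates), exhaustive Fisher-vs-enumeration agreement on all 2×2
tables with row margins ≤ 40 plus 2000 random tables with margins ≤ 60, and
exhaustive label enumeration at n = 8 against 10⁵ Monte-Carlo permutations.
These sizes were chosen so each property is tested at the scale where its
asymptotics or exactness actually bite while the whole suite stays quick to
run.

## Known limitations

- The burden test carries no covariate adjustment (by design, mirroring the
  collapsing-plus-FET method); population stratification within a
  population stratum is uncorrected for rare variants.
- Haplotype association re-uses pooled-EM posterior counts rather than
  re-phasing per stratum or integrating phase uncertainty into the test;
  with strong differential LD between strata this understates uncertainty.
- The permutation p for haplotypes permutes labels over fixed posterior
  counts, so it inherits the same approximation.
- `c.`-style positions are opaque labels; no genomic liftover is attempted,
  and functional annotations are carried as inert metadata only.
- Exact logistic regression, weighted burden tests and variance-component
  tests (e.g. SKAT) are out of scope.
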