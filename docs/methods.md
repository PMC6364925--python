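# Methods

## Scores

Both risk scores assume an additive allelic model. The unweighted score is
the count of risk-increasing alleles over the panel (67 SNPs for CAD, 58 for
LDL-C); the weighted score multiplies each dosage by its GWAS beta and
divides by the mean beta, so both scores live on the 0–2N allele-count scale
and are directly comparable. Orientation happens before scoring: each panel
SNP is located in the genotype data by rsID (falling back to its designated
proxy, r² > 0.8, when the index SNP is absent), and the dosage is flipped
(d → 2 − d) wherever the effect allele is encoded as the reference allele.
Variants whose allele pair does not match the weight table are dropped and
counted in the harmonization report; the report satisfies matched + dropped
= N and proxied ≤ matched by construction.

Strand-ambiguous SNPs (A/T, C/G) cannot be disambiguated by allele identity
alone. The default keeps them with a logged warning — appropriate when all
genotypes come from one platform with consistent strand — and a `drop`
policy is available for mixed-source data.

Missing dosages are handled by one of two policies. `mean_impute` (default)
replaces a missing cell with the variant's in-sample mean dosage, keeping
the effective panel size constant across subjects; `rescale` lets missing
cells contribute zero and scales the subject's score by N/n_used (the
weighted analogue scales by total-beta over observed-beta). The policies
agree in ranking (Spearman ρ > 0.95 at 10% missingness in simulation) but
differ per subject; analyses should state which was used. A subject with
every variant missing gets an undefined score and is excluded downstream
rather than imputed wholesale.

Standardization uses the sample mean and the n−1 SD of the analysis sample
after exclusions. When betas are all equal the weighted score is computed
through the unweighted path, keeping the algebraic identity wGRS = uGRS
exact in floating point rather than to rounding error.

## Cohort analysis

Subjects are stratified by sex-specific age at first revascularization:
men ≤40 / >40–55 / >55–70 / >70 years, women ≤50 / >50–65 / >65–80 / >80,
with boundaries closed on the upper end. (A narrower "very young" convention
of <35/<45 years exists in the literature; the table cutoffs above are the
ones all stratified outputs use.) Premature disease is a first event
strictly before 55 (men) / 65 (women) years.

Trend across the four ordered strata is tested with the Cochran–Armitage
statistic for binary factors — equally spaced scores 1..K, no continuity
correction, normal reference; the statistic is invariant to affine
transformation of the scores and its p-values match both R's
`prop.trend.test` and a permutation null in the test suite — and with an
ordinary linear model on the group index for continuous variables.
Degenerate tables (pooled proportion 0 or 1, or a constant outcome) report
p = 1 with a warning rather than failing.

The regression battery mirrors a two-stage reporting convention: "model 1"
fits each factor separately adjusted for sex (score models additionally for
PCs 1–2); "models 2–5" fit each of the four scores with the full covariate
set (sex, PC1, PC2, familial CAD, smoking, BMI, diabetes, hypertension,
known high cholesterol). All fits are OLS with t-based two-sided p-values
and 95% CIs (df = n − p); rank-deficient designs are fatal and name the
collinear columns. Missing covariates are handled complete-case per model;
two-sided α = 0.05 with no multiple-testing correction. Effect modification
is tested by adding a score × modifier product term to the multivariable
model. The presentation summary tests score differences across STEMI /
NSTEMI / UAP / SAP with one-way ANOVA and the familial-CAD proportion with a
Pearson chi-square — conventional defaults where the choice is open.

Pooled whole-cohort numbers are derived from stratum summaries as n-weighted
means (ages) or pooled counts over total n (percentages). Against the
published reference strata (`grsage.datasets`) this arithmetic reproduces
the whole-sample figures: pooled mean age 64.4 (printed as 64), 27.95% women
(28%), 41.3% familial CAD (41%), and familial-CAD prevalence by presentation
of 32.73% in STEMI and 52.45% in SAP — the latter against a printed 52.5%,
the 0.05-point gap reflecting that the summed stratum denominators (511 SAP)
can differ by a subject or two from the original table's.

## Synthetic cohorts

The generator's defaults are the study conditions, fixed once: 1,599
subjects, 28% women; panels of 67 and 58 SNPs with 3 proxy variants each and
9 SNPs shared between panels; effect-allele frequencies uniform on
[0.05, 0.95]; betas |N(0.08, 0.05)| floored at 0.001. Genotypes are
Binomial(2, p) per subject — Hardy–Weinberg equilibrium with no linkage
disequilibrium between panel SNPs (proxies are modelled as perfect
stand-ins). Age at onset is

    age = μ + γ_cad·z_CAD + γ_ldl·z_LDL + γ_fam·famCAD + γ_sex·female + ε

with μ = 63.8 years, γ_cad = −0.51 and γ_ldl = −0.70 years per SD of the
true weighted scores, γ_fam = −3.2 years, γ_sex = +4.4 years,
ε ~ N(0, 10.5²), truncated to [29, 96] years; the z-scores are computed from
the artifact-free truth matrix with the same code the pipeline uses.
Familial CAD (prevalence 0.41) is drawn independently of the scores, so its
observed age gradient is entirely a consequence of its causal effect.

The other binary risk factors follow logistic age laws (smoking declining,
diabetes/hypertension/cholesterol rising with age) and the presentation
category follows an age-dependent softmax (younger → more STEMI, older →
more stable angina), both driven by the *non-genetic* component of age.
Driving them by realized age would make them mediators of the score → age
effect and bias the multivariable estimates toward zero; with the
non-genetic component the printed age gradients are indistinguishable (the
scores explain ~1% of age variance) while the generator effects remain
recoverable without systematic bias. What bias remains in a single-score
model is real omitted-variable structure: the two scores share SNPs
(r ≈ 0.13), each score model omits the other, and the single-score estimate
absorbs r times the omitted effect (≈ −0.76 observed for the LDL-C score
against a planted −0.70) — the same structure a real cohort analysis of
separately fitted, correlated scores carries.

Artifacts are injected only into the written VCF, never the truth:
missingness at `missing_rate`, ref/alt-swapped encodings at `swap_rate`
(harmonization must flip these back), DS dosage fields on the
proxy/imputed-flagged variants. On an artifact-free bundle the pipeline's
scores equal the generator's latent scores to 1e-10 end to end.

What the generator does **not** emulate: linkage disequilibrium and
realistic allele-frequency spectra, relatedness, genotyping error, the real
joint distribution of risk factors and presentation (the age laws are
qualitative mimics), selection into a catheterization cohort, and any
correlation between familial CAD and the scores. Passing recovery tests
therefore demonstrate that the pipeline estimates what the generative model
plants — not that real-cohort estimates are unconfounded.

## Problem sizes and numerics

Unit tests run on cohorts of 60–300 subjects; distributional checks use
n = 10,000 for one variant. Calibration uses 1,000 null simulations per
trend test (four groups of 200) and 500 coverage simulations (n = 200,
p = 4); parameter recovery uses 200 replicates of n = 1,600, matching the
reference sample size. The acceptance script and the full suite each run in
well under a minute on one CPU. Score vectorization is checked against
brute-force loop oracles to 1e-10; OLS against a pseudo-inverse oracle to
1e-8; standardized scores hit mean 0 / SD 1 to 1e-10. Ties at age-group
boundaries go to the younger stratum (closed upper bounds); zero-variance
inputs to standardization or correlation are fatal rather than silently NaN.
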