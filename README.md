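# grsage

Genetic risk scores and age at onset of coronary artery disease requiring
revascularization.

Clinical cohorts of first-time revascularization patients show large
variation in the age at which coronary artery disease (CAD) first demands
intervention. `grsage` is a tested, reusable pipeline for asking how much of
that variation is carried by known common variants: it builds per-subject
genetic risk scores for CAD and for LDL cholesterol from genotype data and
GWAS effect-weight tables, stratifies a cohort into sex-specific age-at-onset
groups, and estimates the association of the standardized scores (and of
conventional risk factors) with age at onset by linear regression. Because
individual-level clinical genotype data cannot be shared, the package ships a
synthetic-cohort generator with the same statistical structure, so every
pipeline stage is exercised end to end without external data.

## The scores and the models

For subject *i* over the *N* scored SNPs, with s<sub>ij</sub> ∈ [0, 2] the
dosage of the risk-increasing (effect) allele of SNP *j* and β<sub>j</sub>
its GWAS effect size:

- unweighted score: uGRS<sub>i</sub> = Σ<sub>j</sub> s<sub>ij</sub>
- weighted score: wGRS<sub>i</sub> = (N / Σ<sub>j</sub> β<sub>j</sub>) ·
  Σ<sub>j</sub> β<sub>j</sub> s<sub>ij</sub>

The weighted score is normalized by the mean effect size, which keeps it on
the allele-count scale (equal betas make the two scores identical). Before a
score enters the VCF-encoded dosages, `harmonize` orients every variant so
the counted allele is the risk-increasing one — flipping d → 2 − d where the
effect allele is the reference — and substitutes a designated proxy SNP
(linkage disequilibrium r² > 0.8) when an index SNP is absent from the
genotype file.

Scores are standardized to mean 0, SD 1, and age at onset is regressed on
each score with sex and two genetic-ancestry principal components as
covariates (and, in the multivariable models, familial CAD, smoking, BMI,
diabetes, hypertension and known high cholesterol), so coefficients read as
*years of earlier or later onset per SD of score*. Characteristics across
the four sex-specific age strata (men ≤40 / 40–55 / 55–70 / >70 years, women
≤50 / 50–65 / 65–80 / >80) are tested for trend with the Cochran–Armitage
test (binary factors) or a linear model on the group index (continuous ones).

## Worked example

Simulate a 1,599-subject cohort, score it, and run the full analysis:

```sh
printf 'n_subjects = 1599\nseed = 7\n' > sim.cfg
grsage simulate --config sim.cfg --out demo/bundle

printf 'vcf = demo/bundle/genotypes.vcf
weights_cad = demo/bundle/weights_cad.tsv
weights_ldl = demo/bundle/weights_ldl.tsv\n' > score.cfg
grsage score --config score.cfg --out demo/scores

printf 'phenotypes = demo/bundle/phenotypes.tsv
scores_cad = demo/scores/scores_cad.tsv
scores_ldl = demo/scores/scores_ldl.tsv\n' > ana.cfg
grsage analyze --config ana.cfg --out demo/analysis
```

`demo/scores/scores_cad.tsv` holds the per-subject scores (`n_used` counts
the non-missing variants behind each one):

```
subject_id  ugrs  wgrs         z_ugrs         z_wgrs        n_used
S00001      75    71.15108242  0.8006006684   0.04373747907 67
S00002      66    69.56852571  -1.017235277   -0.232893996  67
```

and `demo/analysis/report.txt` contains, among the stratified tables and
interaction tests, the model estimates (years per SD, 95% CI):

```
model1:familial_cad      familial_cad       -2.96 (-4.00, -1.92) p=2.86e-08 n=1599
model1:smoking           smoking            -5.57 (-6.56, -4.57) p=5.17e-27 n=1599
model2:z_wgrs_cad        z_wgrs_cad         -0.42 (-0.89, +0.05) p=0.0812 n=1599
model4:z_wgrs_ldl        z_wgrs_ldl         -0.50 (-0.98, -0.03) p=0.0361 n=1599

correlation wgrs-CAD ~ wgrs-LDL-C: r=0.150 p=1.48e-09
```

Read: in this synthetic cohort, self-reported familial CAD shifts onset 2.96
years earlier (sex-adjusted); each SD of the weighted LDL-C score shifts it
half a year earlier in the fully adjusted model; the two weighted scores are
weakly correlated. These are the structures the generator plants (familial
CAD −3.2 years, LDL-C score −0.70 years/SD, CAD score −0.51 years/SD,
correlation ≈ 0.14 via shared SNPs) recovered by the pipeline from the
simulated VCF and phenotype files, noise included.

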