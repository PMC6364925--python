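"""Synthetic genotype-phenotype cohorts with the study's statistical structure.

The generator emulates a clinical revascularization cohort: biallelic SNP
genotypes drawn under Hardy-Weinberg equilibrium at configurable allele
frequencies, GWAS-magnitude effect weights, and ages at onset that are linear
in the standardized genetic risk scores plus sex, familial-CAD and Gaussian
noise.  Binary risk factors have age-dependent prevalence and the clinical
presentation mixes with age (younger patients more often STEMI).  Defaults
mirror the reference cohort: n=1599 subjects, 28% women, 67 CAD and 58 LDL-C
SNPs (3 proxies each), familial CAD in 41% independent of the scores, true
effects -0.51 / -0.70 years per SD for the CAD / LDL-C scores and -3.2 years
for familial CAD, ages truncated to [29, 96].

Everything is reproducible from ``SimulationConfig.seed``; the file bundle a
run writes (VCF, weight TSVs, phenotype TSV, truth JSON) is consumed by the
CLI exactly as real inputs would be.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genotype_io import (DosageMatrix, VariantKey, WeightEntry, WeightTable,
                          write_vcf, write_weight_table)
from .grs import MissingPolicy, compute_ugrs, compute_wgrs, standardize

CHROMOSOMES = [str(c) for c in range(1, 23)]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort; defaults are the study conditions."""

    n_subjects: int = 1599
    n_snps_cad: int = 67
    n_snps_ldl: int = 58
    #: SNPs shared between the two panels; induces the weak (~0.14)
    #: correlation between the weighted scores.
    n_shared_snps: int = 9
    #: allele-frequency law: uniform on [af_low, af_high]
    af_low: float = 0.05
    af_high: float = 0.95
    #: effect sizes |N(beta_mean, beta_sd)| (GWAS-beta magnitude)
    beta_mean: float = 0.08
    beta_sd: float = 0.05
    #: years of earlier onset per SD of true score (negative = earlier)
    effect_cad: float = -0.51
    effect_ldl: float = -0.70
    #: years of earlier onset with familial CAD
    effect_familial_cad: float = -3.2
    #: years of later onset for women
    effect_female: float = 4.4
    #: baseline mean age at onset for men without familial CAD (years)
    mu_age: float = 63.8
    noise_sd: float = 10.5
    age_min: float = 29.0
    age_max: float = 96.0
    fraction_female: float = 0.28
    familial_cad_prevalence: float = 0.41
    missing_rate: float = 0.0
    swap_rate: float = 0.0
    n_proxies: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_female", "familial_cad_prevalence",
                     "missing_rate", "swap_rate", "af_low", "af_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_snps_cad < 1 or self.n_snps_ldl < 1:
            raise ValueError("each score needs at least 1 SNP")
        if self.n_shared_snps > min(self.n_snps_cad, self.n_snps_ldl):
            raise ValueError("n_shared_snps exceeds a panel size")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class VariantPlan:
    """Generator-side description of one VCF variant."""

    rsid: str            # index rsID used in the weight tables
    vcf_id: str          # id actually written to the VCF (proxy id if proxied)
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    af: float            # effect-allele frequency
    swapped: bool        # VCF encodes effect allele as REF
    imputed: bool        # VCF carries a DS field

    @property
    def ref(self) -> str:
        return self.effect_allele if self.swapped else self.other_allele

    @property
    def alt(self) -> str:
        return self.other_allele if self.swapped else self.effect_allele

    def key(self) -> VariantKey:
        return VariantKey(chrom=self.chrom, pos=self.pos, id=self.vcf_id,
                          ref=self.ref, alt=self.alt)


@dataclass
class SimulatedCohort:
    """In-memory truth for one simulated cohort."""

    config: SimulationConfig
    weights_cad: WeightTable
    weights_ldl: WeightTable
    plans: list[VariantPlan]
    truth_cad: DosageMatrix   # oriented effect-allele dosages, no artifacts
    truth_ldl: DosageMatrix
    phenotypes: pd.DataFrame
    true_z: dict[str, np.ndarray] = field(default_factory=dict)


def _draw_alleles(rng: np.random.Generator) -> tuple[str, str]:
    a, b = rng.choice(list("ACGT"), size=2, replace=False)
    return str(a), str(b)


def generate_weights(config: SimulationConfig,
                     rng: Optional[np.random.Generator] = None
                     ) -> tuple[WeightTable, WeightTable]:
    """Synthetic effect-weight tables for the CAD and LDL-C scores.

    rsIDs are unique; betas are |N(beta_mean, beta_sd)| (floored at 0.001 so
    the normalization is well defined); the last ``n_proxies`` entries of
    each table carry a proxy rsID with r^2 drawn in (0.85, 0.99); the first
    ``n_shared_snps`` LDL entries reuse CAD SNPs to give the two scores a
    weak positive correlation.
    """
    rng = rng or np.random.default_rng(config.seed)

    def _entries(n: int, prefix: str, start: int,
                 shared: list[WeightEntry]) -> list[WeightEntry]:
        entries = list(shared)
        n_new = n - len(shared)
        betas = np.abs(rng.normal(config.beta_mean, config.beta_sd, size=n_new))
        betas = np.maximum(betas, 1e-3)
        for i in range(n_new):
            ea, oa = _draw_alleles(rng)
            entries.append(WeightEntry(id=f"rs{prefix}{start + i}",
                                       effect_allele=ea, other_allele=oa,
                                       beta=float(round(betas[i], 4))))
        # mark the trailing entries as proxied (they stay non-shared)
        for k in range(config.n_proxies):
            j = len(entries) - 1 - k
            if j < len(shared):
                break
            e = entries[j]
            entries[j] = WeightEntry(id=e.id, effect_allele=e.effect_allele,
                                     other_allele=e.other_allele, beta=e.beta,
                                     proxy_id=f"rs{prefix}9{start + 10_000 + k}",
                                     proxy_r2=float(round(rng.uniform(0.85, 0.99), 3)))
        return entries

    cad_entries = _entries(config.n_snps_cad, "10", 100_000, shared=[])
    shared = [dataclasses.replace(e) for e in cad_entries[: config.n_shared_snps]]
    ldl_entries = _entries(config.n_snps_ldl, "20", 200_000, shared=shared)
    return (WeightTable(trait="CAD", entries=tuple(cad_entries)),
            WeightTable(trait="LDL-C", entries=tuple(ldl_entries)))


def plan_variants(config: SimulationConfig, weights_cad: WeightTable,
                  weights_ldl: WeightTable,
                  rng: np.random.Generator) -> list[VariantPlan]:
    """One VariantPlan per unique SNP across both panels (shared SNPs get a
    single plan, hence a single genotype column)."""
    plans: dict[str, VariantPlan] = {}
    i = 0
    for entry in list(weights_cad.entries) + list(weights_ldl.entries):
        if entry.id in plans:
            continue
        plans[entry.id] = VariantPlan(
            rsid=entry.id,
            vcf_id=entry.proxy_id if entry.proxy_id else entry.id,
            chrom=CHROMOSOMES[i % len(CHROMOSOMES)],
            pos=10_000 + 1_000 * (i // len(CHROMOSOMES)) + i,
            effect_allele=entry.effect_allele,
            other_allele=entry.other_allele,
            af=float(rng.uniform(config.af_low, config.af_high)),
            swapped=bool(rng.random() < config.swap_rate),
            imputed=entry.proxy_id is not None,
        )
        i += 1
    return list(plans.values())


def generate_genotypes(
    config: SimulationConfig,
    weights_cad: WeightTable,
    weights_ldl: WeightTable,
    rng: np.random.Generator,
    vcf_path: Optional[str | Path] = None,
) -> tuple[DosageMatrix, DosageMatrix, list[VariantPlan]]:
    """Hardy-Weinberg genotypes for every panel SNP; optionally write a VCF.

    Genotypes are Binomial(2, af) counts of the effect allele.  The returned
    truth matrices (one per trait, columns in weight-table order, oriented)
    are free of artifacts; missingness and ref/alt-swapped encodings are
    injected only into the written VCF at the configured rates.
    """
    plans = plan_variants(config, weights_cad, weights_ldl, rng)
    subjects = [f"S{i:05d}" for i in range(1, config.n_subjects + 1)]
    geno = {p.rsid: rng.binomial(2, p.af, size=config.n_subjects).astype(float)
            for p in plans}

    def _truth(weights: WeightTable) -> DosageMatrix:
        cols = np.column_stack([geno[e.id] for e in weights.entries])
        return DosageMatrix(subject_ids=subjects, variant_ids=list(weights.ids),
                            dosages=cols, oriented=True)

    truth_cad, truth_ldl = _truth(weights_cad), _truth(weights_ldl)

    if vcf_path is not None:
        alt_cols = []
        for p in plans:
            col = geno[p.rsid].copy()
            if p.swapped:
                col = 2.0 - col
            if config.missing_rate > 0:
                col[rng.random(config.n_subjects) < config.missing_rate] = np.nan
            alt_cols.append(col)
        vcf_matrix = DosageMatrix(subject_ids=subjects,
                                  variant_ids=[p.vcf_id for p in plans],
                                  dosages=np.column_stack(alt_cols),
                                  oriented=False)
        write_vcf(vcf_matrix, [p.key() for p in plans], vcf_path,
                  ds_ids={p.vcf_id for p in plans if p.imputed})
    return truth_cad, truth_ldl, plans


#: age-dependent prevalence of the binary risk factors: logistic in
#: (age - 64)/10 with (intercept-logit, slope-per-decade) chosen to mimic the
#: reference tables (smoking declines with age; the others rise).
COVARIATE_AGE_LAWS = {
    "smoking": (0.10, -0.55),
    "diabetes": (-1.85, 0.35),
    "hypertension": (0.05, 0.65),
    "high_cholesterol": (-0.25, 0.25),
}

#: presentation logits at age 64 and their per-decade slopes
PRESENTATION_AGE_LAWS = {
    "STEMI": (0.45, -0.35),
    "NSTEMI": (-0.95, 0.0),
    "UAP": (-1.55, 0.0),
    "SAP": (0.05, 0.35),
}


def generate_phenotypes(
    config: SimulationConfig,
    truth_cad: DosageMatrix,
    truth_ldl: DosageMatrix,
    weights_cad: WeightTable,
    weights_ldl: WeightTable,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Phenotypes with age at onset linear in the true standardized scores.

    age = mu + g_cad z_CAD + g_ldl z_LDL + g_fam famCAD + g_female female + e,
    e ~ N(0, noise_sd^2), truncated to [age_min, age_max].  The z-scores are
    computed from the truth matrices with the same formulas the scoring
    module uses.  Familial CAD is drawn independently of the scores; the
    other binary risk factors and the presentation category are drawn with
    age-dependent laws; PCs are standard normal.
    """
    n = config.n_subjects
    z_cad = standardize(compute_wgrs(truth_cad, weights_cad, MissingPolicy.MEAN_IMPUTE))
    z_ldl = standardize(compute_wgrs(truth_ldl, weights_ldl, MissingPolicy.MEAN_IMPUTE))

    female = (rng.random(n) < config.fraction_female).astype(float)
    fam = (rng.random(n) < config.familial_cad_prevalence).astype(float)
    noise = rng.normal(0.0, config.noise_sd, size=n)
    age_nongenetic = (config.mu_age + config.effect_familial_cad * fam
                      + config.effect_female * female + noise)
    age = (age_nongenetic + config.effect_cad * z_cad + config.effect_ldl * z_ldl)
    age = np.clip(age, config.age_min, config.age_max)

    # covariate prevalences follow the non-genetic age component: the scores
    # explain ~1% of age variance, so the printed age gradients are the same,
    # but the risk factors are not mediators of the score -> age effect and
    # the multivariable models recover the generator effects without bias
    decade = (np.clip(age_nongenetic, config.age_min, config.age_max) - 64.0) / 10.0
    covs = {}
    for name, (a, b) in COVARIATE_AGE_LAWS.items():
        p = 1.0 / (1.0 + np.exp(-(a + b * decade)))
        covs[name] = (rng.random(n) < p).astype(float)

    logits = np.column_stack([a + b * decade for a, b in PRESENTATION_AGE_LAWS.values()])
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    cats = list(PRESENTATION_AGE_LAWS)
    u = rng.random(n)
    idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    presentation = [cats[i] for i in idx]

    df = pd.DataFrame({
        "subject_id": truth_cad.subject_ids,
        "sex": np.where(female == 1.0, "female", "male"),
        "age_onset": np.round(age, 2),
        "familial_cad": fam.astype(int),
        "smoking": covs["smoking"].astype(int),
        "diabetes": covs["diabetes"].astype(int),
        "hypertension": covs["hypertension"].astype(int),
        "high_cholesterol": covs["high_cholesterol"].astype(int),
        "bmi": np.round(rng.normal(27.0, 4.2, size=n), 1),
        "presentation": presentation,
        "pc1": np.round(rng.normal(size=n), 4),
        "pc2": np.round(rng.normal(size=n), 4),
    })
    return df, {"z_cad": z_cad, "z_ldl": z_ldl}


def simulate_truth(config: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort fully in memory (no files) — the fast path for
    recovery and power simulations."""
    rng = np.random.default_rng(config.seed)
    w_cad, w_ldl = generate_weights(config, rng)
    truth_cad, truth_ldl, plans = generate_genotypes(config, w_cad, w_ldl, rng)
    pheno, true_z = generate_phenotypes(config, truth_cad, truth_ldl, w_cad, w_ldl, rng)
    return SimulatedCohort(config=config, weights_cad=w_cad, weights_ldl=w_ldl,
                           plans=plans, truth_cad=truth_cad, truth_ldl=truth_ldl,
                           phenotypes=pheno, true_z=true_z)


@dataclass
class BundlePaths:
    vcf: Path
    weights_cad: Path
    weights_ldl: Path
    phenotypes: Path
    truth: Path


def simulate_cohort(config: SimulationConfig, outdir: str | Path) -> BundlePaths:
    """Write the full file bundle: VCF, two weight TSVs, phenotype TSV and a
    truth JSON recording every generator parameter and per-subject latent
    scores."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    w_cad, w_ldl = generate_weights(config, rng)
    paths = BundlePaths(vcf=outdir / "genotypes.vcf",
                        weights_cad=outdir / "weights_cad.tsv",
                        weights_ldl=outdir / "weights_ldl.tsv",
                        phenotypes=outdir / "phenotypes.tsv",
                        truth=outdir / "truth.json")
    truth_cad, truth_ldl, plans = generate_genotypes(config, w_cad, w_ldl, rng,
                                                     vcf_path=paths.vcf)
    pheno, true_z = generate_phenotypes(config, truth_cad, truth_ldl,
                                        w_cad, w_ldl, rng)
    write_weight_table(w_cad, paths.weights_cad)
    write_weight_table(w_ldl, paths.weights_ldl)
    pheno.to_csv(paths.phenotypes, sep="\t", index=False)

    truth = {
        "config": config.to_dict(),
        "subjects": list(truth_cad.subject_ids),
        "true_z_cad": [round(float(v), 8) for v in true_z["z_cad"]],
        "true_z_ldl": [round(float(v), 8) for v in true_z["z_ldl"]],
        "true_ugrs_cad": compute_ugrs(truth_cad, MissingPolicy.MEAN_IMPUTE,
                                      w_cad).tolist(),
        "true_ugrs_ldl": compute_ugrs(truth_ldl, MissingPolicy.MEAN_IMPUTE,
                                      w_ldl).tolist(),
        "n_swapped": sum(p.swapped for p in plans),
        "n_proxied": sum(p.imputed for p in plans),
    }
    with open(paths.truth, "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths
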