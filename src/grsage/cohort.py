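"""Age-at-onset cohort analysis: stratification, trend tests, regressions.

The cohort is a table of first-time revascularization patients.  Subjects are
stratified into four sex-specific age-at-onset groups (very young / young /
intermediate / old), characteristics are summarized per stratum with tests
for trend (Cochran-Armitage for binary factors, a linear model on the group
index for continuous ones), and the association of standardized genetic risk
scores with age at onset is estimated by ordinary least squares with sex and
genetic principal components (and, in the multivariable models, the clinical
risk factors) as covariates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genotype_io import Sex
from .grs import ScoreSet

logger = logging.getLogger(__name__)


class AnalysisError(ValueError):
    pass


class AgeGroup(str, Enum):
    VERY_YOUNG = "very_young"
    YOUNG = "young"
    INTERMEDIATE = "intermediate"
    OLD = "old"


#: Upper bounds (inclusive) of the first three sex-specific age groups, years.
AGE_CUTOFFS: dict[Sex, tuple[float, float, float]] = {
    Sex.MALE: (40.0, 55.0, 70.0),
    Sex.FEMALE: (50.0, 65.0, 80.0),
}

#: Premature disease: first event before this age (strict), by sex.
PREMATURE_CUTOFF: dict[Sex, float] = {Sex.MALE: 55.0, Sex.FEMALE: 65.0}

GROUP_ORDER = [AgeGroup.VERY_YOUNG, AgeGroup.YOUNG, AgeGroup.INTERMEDIATE, AgeGroup.OLD]


def assign_age_group(sex: Sex | str, age_onset: float) -> AgeGroup:
    """Sex-specific age-at-onset stratum; boundaries inclusive on the upper
    end (a 40.0-year-old man is very young, a 40.01-year-old is young)."""
    c1, c2, c3 = AGE_CUTOFFS[Sex(sex)]
    if age_onset <= c1:
        return AgeGroup.VERY_YOUNG
    if age_onset <= c2:
        return AgeGroup.YOUNG
    if age_onset <= c3:
        return AgeGroup.INTERMEDIATE
    return AgeGroup.OLD


def flag_premature(sex: Sex | str, age_onset: float) -> bool:
    """True iff onset strictly before 55 (men) / 65 (women) years."""
    return age_onset < PREMATURE_CUTOFF[Sex(sex)]


# ---------------------------------------------------------------------------
# tests


@dataclass
class TrendResult:
    """Outcome of a test for trend across ordered groups."""

    statistic: float
    p: float
    group_ns: list[int]
    group_values: list[float]  # proportions (binary) or means (continuous)
    slope: Optional[float] = None
    se: Optional[float] = None


def cochran_armitage_trend(
    successes: Sequence[int],
    totals: Sequence[int],
    scores: Optional[Sequence[float]] = None,
) -> TrendResult:
    """Cochran-Armitage test for linear trend in proportions.

    Z = sum_k w_k (r_k - n_k pbar) /
        sqrt(pbar (1-pbar) [sum n_k w_k^2 - (sum n_k w_k)^2 / N])

    with group scores w_k (default 1..K equally spaced), pooled proportion
    pbar, and a two-sided p from the standard normal; no continuity
    correction.  The statistic is invariant to affine rescaling of scores.
    """
    r = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if len(r) != len(n) or len(r) < 2:
        raise AnalysisError("need >= 2 groups with matching successes/totals")
    if (n <= 0).any():
        raise AnalysisError("every group total must be positive")
    if ((r < 0) | (r > n)).any():
        raise AnalysisError("successes must satisfy 0 <= r_k <= n_k")
    w = np.arange(1.0, len(r) + 1.0) if scores is None else np.asarray(scores, dtype=float)

    N = n.sum()
    pbar = r.sum() / N
    props = (r / n).tolist()
    if pbar in (0.0, 1.0):
        logger.warning("degenerate trend table (pooled proportion %s); p = 1", pbar)
        return TrendResult(statistic=0.0, p=1.0, group_ns=[int(x) for x in n],
                           group_values=props)
    num = float(np.sum(w * (r - n * pbar)))
    var = pbar * (1 - pbar) * (np.sum(n * w ** 2) - np.sum(n * w) ** 2 / N)
    z = num / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return TrendResult(statistic=float(z), p=float(p),
                       group_ns=[int(x) for x in n], group_values=props)


def continuous_trend_test(values: Sequence[float], group_index: Sequence[int]) -> TrendResult:
    """Linear-model trend for a continuous variable: OLS of the value on the
    (1..K) group index; slope, SE and the two-sided t-test p are returned."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(group_index, dtype=float)
    keep = np.isfinite(y) & np.isfinite(g)
    y, g = y[keep], g[keep]
    levels = np.unique(g)
    if levels.size < 2:
        raise AnalysisError("need >= 2 non-empty groups")
    group_ns = [int((g == lv).sum()) for lv in levels]
    group_means = [float(y[g == lv].mean()) for lv in levels]
    if np.ptp(y) == 0:
        logger.warning("all values identical; trend p undefined, reported as 1")
        return TrendResult(statistic=0.0, p=1.0, group_ns=group_ns,
                           group_values=group_means, slope=0.0, se=np.nan)
    X = sm.add_constant(g)
    fit = sm.OLS(y, X).fit()
    return TrendResult(statistic=float(fit.tvalues[1]), p=float(fit.pvalues[1]),
                       group_ns=group_ns, group_values=group_means,
                       slope=float(fit.params[1]), se=float(fit.bse[1]))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with the usual t-based two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise AnalysisError("need equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise AnalysisError("zero variance in one of the inputs")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# linear models


@dataclass
class ModelFit:
    """A fitted linear model: per-term estimates, 95% CIs and p-values."""

    model: str
    terms: list[str]
    estimates: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    n: int

    def term(self, name: str) -> dict[str, float]:
        i = self.terms.index(name)
        return {"estimate": float(self.estimates[i]), "se": float(self.se[i]),
                "ci_low": float(self.ci_low[i]), "ci_high": float(self.ci_high[i]),
                "p": float(self.p[i]), "n": self.n}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": self.model, "term": self.terms,
            "estimate": self.estimates, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p": self.p, "n": self.n,
        })


def fit_ols(
    response: Sequence[float],
    design: pd.DataFrame | np.ndarray,
    terms: Optional[Sequence[str]] = None,
    model: str = "ols",
    add_intercept: bool = True,
) -> ModelFit:
    """OLS with t-based 95% CIs and two-sided p-values (df = n - p).

    The design must be full rank and n > p; rank-deficiency is fatal and
    names the collinear columns.
    """
    y = np.asarray(response, dtype=float)
    if isinstance(design, pd.DataFrame):
        labels = list(design.columns) if terms is None else list(terms)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        labels = list(terms) if terms is not None else [f"x{j}" for j in range(X.shape[1])]
    if X.ndim == 1:
        X = X[:, None]
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        labels = ["intercept"] + labels

    n, p = X.shape
    if n <= p:
        raise AnalysisError(f"n={n} <= p={p}; cannot fit")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        bad = _collinear_terms(X, labels)
        raise AnalysisError(f"rank-deficient design (rank {rank} < {p}); "
                           f"collinear terms: {bad}")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return ModelFit(model=model, terms=labels,
                    estimates=np.asarray(fit.params), se=np.asarray(fit.bse),
                    ci_low=np.asarray(ci)[:, 0], ci_high=np.asarray(ci)[:, 1],
                    p=np.asarray(fit.pvalues), n=n)


def _collinear_terms(X: np.ndarray, labels: list[str]) -> list[str]:
    # columns whose removal raises the rank deficit are the culprits
    full_rank = np.linalg.matrix_rank(X)
    bad = []
    for j in range(X.shape[1]):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            bad.append(labels[j])
    return bad or labels


# ---------------------------------------------------------------------------
# the study's model battery

SCORE_COLUMNS = {
    "z_wgrs_cad": "wGRS-CAD", "z_ugrs_cad": "uGRS-CAD",
    "z_wgrs_ldl": "wGRS-LDL-C", "z_ugrs_ldl": "uGRS-LDL-C",
}
RISK_FACTORS = ["familial_cad", "smoking", "bmi", "diabetes", "hypertension",
                "high_cholesterol"]
FULL_COVARIATES = ["female", "pc1", "pc2", "familial_cad", "smoking", "bmi",
                   "diabetes", "hypertension", "high_cholesterol"]


def join_scores(pheno: pd.DataFrame, scores: Mapping[str, ScoreSet]) -> pd.DataFrame:
    """Join standardized score columns onto the phenotype frame by subject id.

    ``scores`` maps a trait key ('cad', 'ldl') to its ScoreSet; the output
    gains z_ugrs_<key> / z_wgrs_<key> (and raw ugrs_/wgrs_) columns.
    """
    out = pheno.copy()
    for trait_key, ss in scores.items():
        sf = ss.to_frame()
        for col in ("ugrs", "wgrs", "z_ugrs", "z_wgrs"):
            out[f"{col}_{trait_key}"] = out["subject_id"].map(sf[col])
    return out


def grs_age_models(df: pd.DataFrame) -> list[ModelFit]:
    """Fit the study's model battery on a cohort with joined score columns.

    Model 1 (one fit per factor): age at onset on the factor plus sex;
    genetic-score models are additionally adjusted for PCs 1-2.  Models 2-5:
    age at onset on each standardized score (wGRS-CAD, uGRS-CAD, wGRS-LDL-C,
    uGRS-LDL-C) with the full covariate set (sex, PC1, PC2, familial CAD,
    smoking, BMI, diabetes, hypertension, known high cholesterol).
    Complete-case analysis per model; a model whose factor is entirely
    missing is skipped with a log entry.
    """
    fits: list[ModelFit] = []
    for factor in RISK_FACTORS:
        fit = _fit_complete_case(df, factor, ["female"], f"model1:{factor}")
        if fit is not None:
            fits.append(fit)
    for col in SCORE_COLUMNS:
        fit = _fit_complete_case(df, col, ["female", "pc1", "pc2"], f"model1:{col}")
        if fit is not None:
            fits.append(fit)
    for number, col in zip((2, 3, 4, 5), SCORE_COLUMNS):
        covars = [c for c in FULL_COVARIATES]
        fit = _fit_complete_case(df, col, covars, f"model{number}:{col}")
        if fit is not None:
            fits.append(fit)
    return fits


def _fit_complete_case(df: pd.DataFrame, focus: str, covariates: list[str],
                       label: str) -> Optional[ModelFit]:
    cols = [focus] + [c for c in covariates if c != focus]
    sub = df[["age_onset"] + cols].dropna()
    if sub.empty or sub[focus].isna().all() or len(sub) <= len(cols) + 1:
        logger.warning("model %s skipped: no usable observations for %s", label, focus)
        return None
    return fit_ols(sub["age_onset"], sub[cols], model=label)


def interaction_test(df: pd.DataFrame, score_col: str, modifier: str) -> ModelFit:
    """Effect modification: the full multivariable model augmented with a
    score x modifier product term; the fit exposes the product term's
    estimate and p via ``.term(f"{score_col}:{modifier}")``."""
    covars = [c for c in FULL_COVARIATES if c != modifier] + [modifier]
    cols = [score_col] + covars
    sub = df[["age_onset"] + cols].dropna().copy()
    product = f"{score_col}:{modifier}"
    sub[product] = sub[score_col] * sub[modifier]
    return fit_ols(sub["age_onset"], sub[cols + [product]],
                   model=f"interaction:{product}")


# ---------------------------------------------------------------------------
# tables

CONTINUOUS_ROWS = ["age_onset", "bmi", "ugrs_cad", "wgrs_cad", "ugrs_ldl", "wgrs_ldl"]
BINARY_ROWS = ["smoking", "diabetes", "hypertension", "high_cholesterol", "familial_cad"]
PRESENTATION_ORDER = ["STEMI", "NSTEMI", "UAP", "SAP"]


def characteristics_table(df: pd.DataFrame, sex: Sex | str) -> pd.DataFrame:
    """Per-age-group characteristics for one sex, with trend p-values.

    Continuous rows give mean (SD) and a linear-model trend p; binary and
    presentation rows give count (%) and a Cochran-Armitage trend p.  An
    empty stratum appears with n=0 and no test contribution.
    """
    sex = Sex(sex)
    sub = df[df["female"] == (1.0 if sex is Sex.FEMALE else 0.0)].copy()
    sub["age_group"] = [assign_age_group(sex, a).value for a in sub["age_onset"]]
    groups = [g.value for g in GROUP_ORDER]
    ns = {g: int((sub["age_group"] == g).sum()) for g in groups}

    rows: list[dict] = [{"row": "n", **{g: ns[g] for g in groups}, "p_trend": np.nan}]
    nonempty = [g for g in groups if ns[g] > 0]

    for var in CONTINUOUS_ROWS:
        if var not in sub.columns:
            continue
        cells, vals, idx = {}, [], []
        for k, g in enumerate(groups, start=1):
            x = sub.loc[sub["age_group"] == g, var].dropna()
            cells[g] = f"{x.mean():.1f} ({x.std(ddof=1):.1f})" if len(x) else ""
            vals.extend(x)
            idx.extend([k] * len(x))
        p = np.nan
        if var != "age_onset" and len(set(idx)) >= 2:
            p = continuous_trend_test(vals, idx).p
        rows.append({"row": var, **cells, "p_trend": p})

    def _binary_row(name: str, indicator: pd.Series) -> dict:
        cells, succ, tot = {}, [], []
        for g in groups:
            mask = sub["age_group"] == g
            x = indicator[mask].dropna()
            if len(x):
                r = int(x.sum())
                cells[g] = f"{r} ({100.0 * r / len(x):.1f})"
                succ.append(r)
                tot.append(len(x))
            else:
                cells[g] = ""
        p = cochran_armitage_trend(succ, tot).p if len(tot) >= 2 else np.nan
        return {"row": name, **cells, "p_trend": p}

    for var in BINARY_ROWS:
        if var in sub.columns:
            rows.append(_binary_row(var, sub[var]))
    if "presentation" in sub.columns and sub["presentation"].notna().any():
        for pres in PRESENTATION_ORDER:
            indicator = sub["presentation"].map(
                lambda v: np.nan if v is None or (isinstance(v, float) and np.isnan(v))
                else float(v == pres))
            rows.append(_binary_row(pres, indicator))

    if not nonempty:
        logger.warning("characteristics_table: no %s subjects", sex.value)
    return pd.DataFrame(rows, columns=["row"] + groups + ["p_trend"])


def presentation_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Score means (SD) and familial-CAD prevalence by clinical presentation.

    'P for difference' is a one-way ANOVA F-test for the score rows and a
    Pearson chi-square for the familial-CAD row.
    """
    sub = df[df["presentation"].notna()].copy()
    present = [p for p in PRESENTATION_ORDER if (sub["presentation"] == p).any()]
    absent = set(PRESENTATION_ORDER) - set(present)
    if absent:
        logger.warning("presentation categories absent: %s", sorted(absent))
    if len(present) < 2:
        raise AnalysisError("need >= 2 presentation categories")

    rows = []
    for var in ("ugrs_cad", "wgrs_cad", "ugrs_ldl", "wgrs_ldl"):
        if var not in sub.columns:
            continue
        cells, samples = {}, []
        for p in present:
            x = sub.loc[sub["presentation"] == p, var].dropna()
            cells[p] = f"{x.mean():.1f} ({x.std(ddof=1):.1f})"
            samples.append(x.to_numpy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fstat, pval = stats.f_oneway(*samples)
        rows.append({"row": var, **cells, "p_diff": float(pval)})

    if "familial_cad" in sub.columns:
        cells, table = {}, []
        for p in present:
            x = sub.loc[sub["presentation"] == p, "familial_cad"].dropna()
            r = int(x.sum())
            cells[p] = f"{r} ({100.0 * r / len(x):.1f})"
            table.append([r, len(x) - r])
        chi2, pval, _, _ = stats.chi2_contingency(np.array(table).T, correction=False)
        rows.append({"row": "familial_cad", **cells, "p_diff": float(pval)})
    return pd.DataFrame(rows, columns=["row"] + present + ["p_diff"])


def derived_overall_summary(strata: pd.DataFrame) -> dict[str, float]:
    """Pool sex-by-age stratum summaries into whole-cohort numbers.

    ``strata`` needs columns ``sex`` ('male'/'female'), ``n`` and
    ``mean_age``; any column named ``<factor>_n`` is pooled into a
    percentage ``pct_<factor>``.  The pooled mean age is the n-weighted
    average of stratum means; percentages are pooled counts over total n.
    """
    if strata["n"].isna().any():
        raise AnalysisError("every stratum needs an n")
    n = strata["n"].to_numpy(dtype=float)
    total = n.sum()
    out = {
        "n_total": float(total),
        "pooled_mean_age": float((n * strata["mean_age"]).sum() / total),
        "pct_women": float(100.0 * n[(strata["sex"] == "female").to_numpy()].sum() / total),
    }
    for col in strata.columns:
        if col.endswith("_n") and col != "n":
            out[f"pct_{col[:-2]}"] = float(100.0 * strata[col].sum() / total)
    return out
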