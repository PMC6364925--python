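"""Unweighted and weighted genetic risk scores.

The unweighted score of subject *i* is the plain risk-allele count

    uGRS_i = sum_j s_ij

over the N scored SNPs, where s_ij in [0, 2] is the effect-allele dosage.
The weighted score multiplies each dosage by its GWAS beta and renormalizes
by the mean beta, which puts it back on the allele-count scale:

    wGRS_i = (N / sum_j beta_j) * sum_j beta_j * s_ij

so that with equal betas wGRS == uGRS exactly.  Scores are standardized to
sample mean 0 and SD 1 (n-1 denominator) before regression, so model
coefficients read as years per SD of score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import DosageMatrix, WeightTable

logger = logging.getLogger(__name__)


class GRSError(ValueError):
    pass


class MissingPolicy(str, Enum):
    """How missing dosages enter a score.

    ``mean_impute`` replaces each missing cell with the variant's in-sample
    mean dosage; ``rescale`` lets missing cells contribute 0 and scales the
    subject's score back up to the full panel (N / n_used for the unweighted
    score, total-beta over observed-beta analogously for the weighted one).
    """

    MEAN_IMPUTE = "mean_impute"
    RESCALE = "rescale"


@dataclass
class ScoreSet:
    """Per-subject scores for one trait, raw and standardized."""

    trait: str
    subject_ids: list[str]
    ugrs: np.ndarray
    wgrs: np.ndarray
    z_ugrs: np.ndarray
    z_wgrs: np.ndarray
    n_used: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": self.subject_ids,
            "ugrs": self.ugrs, "wgrs": self.wgrs,
            "z_ugrs": self.z_ugrs, "z_wgrs": self.z_wgrs,
            "n_used": self.n_used,
        }).set_index("subject_id", drop=False)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _check_oriented(matrix: DosageMatrix) -> None:
    if not matrix.oriented:
        raise GRSError("dosage matrix must be oriented (run harmonize first)")


def apply_missing_policy(
    matrix: DosageMatrix, weights: WeightTable, policy: MissingPolicy | str
) -> DosageMatrix:
    """Complete a matrix under ``mean_impute``; pass through under ``rescale``
    (rescaling happens at scoring time, per subject)."""
    _check_oriented(matrix)
    policy = MissingPolicy(policy)
    if policy is MissingPolicy.RESCALE:
        return matrix
    dosages = matrix.dosages.copy()
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        mask = np.isnan(col)
        if not mask.any():
            continue
        if mask.all():
            raise GRSError(
                f"variant {matrix.variant_ids[j]} missing in all subjects; "
                "cannot mean-impute"
            )
        col[mask] = col[~mask].mean()
    return DosageMatrix(subject_ids=list(matrix.subject_ids),
                        variant_ids=list(matrix.variant_ids),
                        dosages=dosages, oriented=True)


def compute_ugrs(matrix: DosageMatrix, policy: MissingPolicy | str = MissingPolicy.MEAN_IMPUTE,
                 weights: WeightTable | None = None) -> np.ndarray:
    """Unweighted score: row sum of effect-allele dosages after the missing
    policy.  Subjects with every variant missing get NaN (flagged for
    downstream exclusion)."""
    _check_oriented(matrix)
    policy = MissingPolicy(policy)
    dosages = matrix.dosages
    all_missing = np.isnan(dosages).all(axis=1)
    if policy is MissingPolicy.MEAN_IMPUTE:
        if weights is None:
            weights = _unit_weights(matrix)
        completed = apply_missing_policy(matrix, weights, policy)
        scores = completed.dosages.sum(axis=1)
    else:
        n_total = dosages.shape[1]
        n_used = (~np.isnan(dosages)).sum(axis=1)
        with np.errstate(invalid="ignore"):
            scores = np.nansum(dosages, axis=1) * (n_total / np.maximum(n_used, 1))
    scores = np.asarray(scores, dtype=float)
    scores[all_missing] = np.nan
    if all_missing.any():
        logger.warning("%d subject(s) with all variants missing; score undefined",
                       int(all_missing.sum()))
    return scores


def compute_wgrs(matrix: DosageMatrix, weights: WeightTable,
                 policy: MissingPolicy | str = MissingPolicy.MEAN_IMPUTE) -> np.ndarray:
    """Weighted score normalized by the mean beta (allele-count scale)."""
    _check_oriented(matrix)
    policy = MissingPolicy(policy)
    if list(matrix.variant_ids) != weights.ids:
        raise GRSError("matrix columns are not aligned with the weight table")
    betas = weights.betas
    beta_sum = betas.sum()
    if beta_sum == 0:
        raise GRSError("sum of betas is zero; normalization undefined")
    if (betas < 0).any():
        logger.warning("%s: %d negative beta(s) after orientation",
                       weights.trait, int((betas < 0).sum()))

    dosages = matrix.dosages
    all_missing = np.isnan(dosages).all(axis=1)
    N = weights.N
    if np.ptp(betas) == 0:
        # equal betas: the normalization cancels algebraically, so take the
        # unweighted path to keep wGRS == uGRS exact rather than to rounding
        return compute_ugrs(matrix, policy, weights)
    if policy is MissingPolicy.MEAN_IMPUTE:
        completed = apply_missing_policy(matrix, weights, policy)
        scores = (N / beta_sum) * (completed.dosages * betas).sum(axis=1)
    else:
        observed = ~np.isnan(dosages)
        weighted = np.nansum(dosages * betas, axis=1)
        beta_obs = observed @ betas
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = N * weighted / beta_obs
    scores = np.asarray(scores, dtype=float)
    scores[all_missing] = np.nan
    return scores


def standardize(scores: np.ndarray) -> np.ndarray:
    """z = (x - mean) / SD with the n-1 sample SD; NaN entries are ignored
    for the moments and preserved in the output."""
    scores = np.asarray(scores, dtype=float)
    valid = scores[np.isfinite(scores)]
    if valid.size < 2:
        raise GRSError("standardization needs at least 2 non-missing scores")
    sd = valid.std(ddof=1)
    if sd == 0:
        raise GRSError("scores have zero variance; cannot standardize")
    return (scores - valid.mean()) / sd


def score_cohort(matrix: DosageMatrix, weights: WeightTable,
                 policy: MissingPolicy | str = MissingPolicy.MEAN_IMPUTE) -> ScoreSet:
    """Compute uGRS/wGRS and their standardized versions for one trait."""
    _check_oriented(matrix)
    n_used = (~np.isnan(matrix.dosages)).sum(axis=1)
    ugrs = compute_ugrs(matrix, policy, weights)
    wgrs = compute_wgrs(matrix, weights, policy)
    return ScoreSet(trait=weights.trait,
                    subject_ids=list(matrix.subject_ids),
                    ugrs=ugrs, wgrs=wgrs,
                    z_ugrs=standardize(ugrs), z_wgrs=standardize(wgrs),
                    n_used=n_used)


def _unit_weights(matrix: DosageMatrix) -> WeightTable:
    # internal helper so compute_ugrs can reuse apply_missing_policy
    from .genotype_io import WeightEntry
    entries = tuple(WeightEntry(id=v, effect_allele="A", other_allele="G", beta=1.0)
                    for v in matrix.variant_ids)
    return WeightTable(trait="unit", entries=entries)
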