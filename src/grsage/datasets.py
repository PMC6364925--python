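"""Published summary statistics of the reference clinical cohort.

These are the printed sex-by-age stratum summaries of a Danish cohort of
1,599 patients undergoing first-time coronary revascularization (men
stratified at <=40 / 40-55 / 55-70 / >70 years, women at <=50 / 50-65 /
65-80 / >80), plus the familial-CAD counts by clinical presentation.  They
serve two purposes: checking the pooled-summary arithmetic
(:func:`grsage.cohort.derived_overall_summary`) against the cohort's
published whole-sample figures, and anchoring the synthetic generator's
default parameters to realistic values.
"""

from __future__ import annotations

import pandas as pd

#: sex, age-group label, n, mean age (y), familial-CAD count, smoking count,
#: and presentation counts (STEMI/NSTEMI/UAP/SAP) per stratum.
_STRATA = [
    # sex,      group,          n,  mean_age, fam, smoke, stemi, nstemi, uap, sap
    ("male",   "very_young",   10, 36.9,   5,   7,   8,  1,  0,   1),
    ("male",   "young",       297, 49.8, 144, 176, 179, 33, 14,  71),
    ("male",   "intermediate", 537, 63.3, 216, 299, 267, 68, 36, 166),
    ("male",   "old",          308, 76.6,  83, 125, 128, 32, 24, 124),
    ("female", "very_young",    36, 45.5,  15,  26,  20,  4,  3,   9),
    ("female", "young",        153, 58.3,  80,  99,  73, 23, 12,  45),
    ("female", "intermediate", 188, 72.7,  93,  80,  62, 36, 16,  74),
    ("female", "old",           70, 85.1,  25,  26,  39,  8,  2,  21),
]

#: familial-CAD counts by clinical presentation (whole cohort).
PRESENTATION_FAMILIAL_CAD = {"STEMI": 254, "NSTEMI": 88, "UAP": 51, "SAP": 268}


def reference_strata() -> pd.DataFrame:
    """The eight published sex-by-age stratum summaries as a DataFrame with
    columns sex, group, n, mean_age, familial_cad_n, smoking_n and the four
    presentation counts."""
    return pd.DataFrame(
        _STRATA,
        columns=["sex", "group", "n", "mean_age", "familial_cad_n", "smoking_n",
                 "STEMI_n", "NSTEMI_n", "UAP_n", "SAP_n"],
    )


def presentation_totals() -> dict[str, int]:
    """Total subjects per clinical presentation, summed over the strata."""
    df = reference_strata()
    return {p: int(df[f"{p}_n"].sum()) for p in ("STEMI", "NSTEMI", "UAP", "SAP")}


def familial_cad_by_presentation() -> dict[str, float]:
    """Percent with familial CAD within each presentation category."""
    totals = presentation_totals()
    return {p: 100.0 * PRESENTATION_FAMILIAL_CAD[p] / totals[p] for p in totals}
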