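"""Stratification, trend tests, regressions and summary tables."""

import numpy as np
import pandas as pd
import pytest

from grsage.cohort import (AgeGroup, AnalysisError, assign_age_group,
                           characteristics_table, cochran_armitage_trend,
                           continuous_trend_test, derived_overall_summary,
                           fit_ols, flag_premature, grs_age_models,
                           interaction_test, join_scores, pearson_correlation,
                           presentation_summary)
from grsage.datasets import (familial_cad_by_presentation,
                             presentation_totals, reference_strata,
                             PRESENTATION_FAMILIAL_CAD)
from grsage.genotype_io import Sex
from grsage.grs import score_cohort


@pytest.mark.parametrize("sex, age, expected", [
    ("male", 36.9, AgeGroup.VERY_YOUNG),
    ("male", 40.0, AgeGroup.VERY_YOUNG),
    ("male", 40.01, AgeGroup.YOUNG),
    ("male", 55.0, AgeGroup.YOUNG),
    ("male", 63.3, AgeGroup.INTERMEDIATE),
    ("male", 70.01, AgeGroup.OLD),
    ("female", 45.5, AgeGroup.VERY_YOUNG),
    ("female", 50.0, AgeGroup.VERY_YOUNG),
    ("female", 58.3, AgeGroup.YOUNG),
    ("female", 80.0, AgeGroup.INTERMEDIATE),
    ("female", 85.1, AgeGroup.OLD),
])
def test_age_group_boundaries(sex, age, expected):
    assert assign_age_group(sex, age) is expected


@pytest.mark.parametrize("sex, age, expected", [
    ("male", 54.9, True), ("male", 55.0, False),
    ("female", 64.9, True), ("female", 65.0, False),
])
def test_premature_is_strict(sex, age, expected):
    assert flag_premature(sex, age) is expected


# ---------------------------------------------------------------------------
# trend tests


def test_ca_trend_null_by_symmetry():
    r = cochran_armitage_trend([5, 50, 25], [10, 100, 50])
    assert r.statistic == pytest.approx(0.0, abs=1e-12)
    assert r.p == pytest.approx(1.0)


def test_ca_trend_on_published_smoking_counts():
    """Male smoking declines 70% -> 40.6% across age groups: p < 0.001."""
    r = cochran_armitage_trend([7, 176, 299, 125], [10, 297, 537, 308])
    assert r.p < 0.001
    assert r.statistic < 0  # declining trend


def test_ca_trend_affine_score_invariance():
    succ, tot = [3, 10, 20, 9], [12, 30, 45, 20]
    base = cochran_armitage_trend(succ, tot)
    shifted = cochran_armitage_trend(succ, tot, scores=[10, 30, 50, 70])
    assert shifted.statistic == pytest.approx(base.statistic, abs=1e-12)
    assert shifted.p == pytest.approx(base.p, abs=1e-12)


def test_ca_trend_matches_permutation_null(rng):
    """Two-sided p agrees with a 20,000-draw permutation null of the same
    statistic within Monte-Carlo error."""
    succ, tot = [4, 8, 9, 12], [15, 18, 16, 17]
    obs = cochran_armitage_trend(succ, tot)
    labels = np.repeat(np.arange(4), tot)
    outcomes = np.concatenate([np.r_[np.ones(r), np.zeros(n - r)]
                               for r, n in zip(succ, tot)])
    n_perm = 20_000
    stats_perm = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(outcomes)
        r_b = [int(perm[labels == k].sum()) for k in range(4)]
        stats_perm[b] = cochran_armitage_trend(r_b, tot).statistic
    p_perm = np.mean(np.abs(stats_perm) >= abs(obs.statistic) - 1e-12)
    mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm)
    assert obs.p == pytest.approx(p_perm, abs=mc_err + 0.02)


def test_ca_trend_degenerate_and_errors():
    r = cochran_armitage_trend([0, 0], [10, 10])
    assert r.p == 1.0
    with pytest.raises(AnalysisError):
        cochran_armitage_trend([1, 0], [10, 0])
    with pytest.raises(AnalysisError):
        cochran_armitage_trend([11], [10])


def test_continuous_trend_flat_and_exact():
    flat = continuous_trend_test([1.0, 2.0, 1.0, 2.0], [1, 1, 2, 2])
    assert flat.slope == pytest.approx(0.0, abs=1e-12)
    exact = continuous_trend_test([3.0, 3.0, 5.0, 5.0, 7.0, 7.0], [1, 1, 2, 2, 3, 3])
    assert exact.slope == pytest.approx(2.0, abs=1e-10)
    assert exact.p < 1e-10
    const = continuous_trend_test([4.0, 4.0, 4.0, 4.0], [1, 1, 2, 2])
    assert const.p == 1.0


def test_pearson_identity_and_hand_oracle():
    x = np.arange(10.0)
    r, p = pearson_correlation(x, x)
    assert r == pytest.approx(1.0)
    # hand-worked: x=(1,2,3,4), y=(2,1,4,3) -> r = 0.6
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([2.0, 1.0, 4.0, 3.0])
    sx, sy = x - x.mean(), y - y.mean()
    r_hand = (sx * sy).sum() / np.sqrt((sx ** 2).sum() * (sy ** 2).sum())
    r, p = pearson_correlation(x, y)
    assert r == pytest.approx(r_hand, abs=1e-12)
    with pytest.raises(AnalysisError, match="zero variance"):
        pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# OLS


def test_fit_ols_exact_line():
    x = np.arange(10.0)
    fit = fit_ols(2.0 + 3.0 * x, x[:, None], ["x"], model="exact")
    assert fit.term("intercept")["estimate"] == pytest.approx(2.0, abs=1e-10)
    assert fit.term("x")["estimate"] == pytest.approx(3.0, abs=1e-10)


def test_fit_ols_matches_pinv_oracle(rng):
    n, p = 200, 4
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    fit = fit_ols(y, X, [f"x{j}" for j in range(p)])
    Xd = np.column_stack([np.ones(n), X])
    beta = np.linalg.pinv(Xd) @ y
    np.testing.assert_allclose(fit.estimates, beta, atol=1e-8)
    resid = y - Xd @ beta
    sigma2 = resid @ resid / (n - p - 1)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(Xd.T @ Xd)))
    np.testing.assert_allclose(fit.se, se, atol=1e-8)
    from scipy.stats import t as tdist
    tcrit = tdist.ppf(0.975, n - p - 1)
    np.testing.assert_allclose(fit.ci_high - fit.estimates, tcrit * se, atol=1e-8)


def test_fit_ols_rank_deficiency_names_terms(rng):
    x = rng.normal(size=50)
    X = np.column_stack([x, 2 * x])
    with pytest.raises(AnalysisError, match="collinear") as err:
        fit_ols(rng.normal(size=50), X, ["a", "b"])
    assert "a" in str(err.value) and "b" in str(err.value)
    with pytest.raises(AnalysisError, match="n="):
        fit_ols([1.0, 2.0], np.ones((2, 3)), ["a", "b", "c"])


# ---------------------------------------------------------------------------
# study battery on simulated cohorts


def _analysis_frame(sim):
    ss_cad = score_cohort(sim.truth_cad, sim.weights_cad)
    ss_ldl = score_cohort(sim.truth_ldl, sim.weights_ldl)
    ph = sim.phenotypes.copy()
    ph["female"] = (ph["sex"] == "female").astype(float)
    ph = ph.set_index("subject_id", drop=False)
    return join_scores(ph, {"cad": ss_cad, "ldl": ss_ldl})


def test_grs_age_models_battery_shape(small_truth):
    df = _analysis_frame(small_truth)
    fits = grs_age_models(df)
    labels = [f.model for f in fits]
    assert len([l for l in labels if l.startswith("model1:")]) == 10
    for number, col in zip((2, 3, 4, 5),
                           ("z_wgrs_cad", "z_ugrs_cad", "z_wgrs_ldl", "z_ugrs_ldl")):
        fit = next(f for f in fits if f.model == f"model{number}:{col}")
        assert set(["female", "pc1", "pc2", "smoking", "bmi"]) < set(fit.terms)
        assert fit.term(col)["ci_low"] < fit.term(col)["estimate"] < fit.term(col)["ci_high"]


def test_interaction_constant_modifier_is_rank_deficient(small_truth):
    df = _analysis_frame(small_truth).copy()
    df["smoking"] = 1.0
    with pytest.raises(AnalysisError, match="collinear|rank"):
        interaction_test(df, "z_wgrs_cad", "smoking")


def test_characteristics_table_bookkeeping(small_truth):
    df = _analysis_frame(small_truth)
    total = 0
    for sex in ("male", "female"):
        table = characteristics_table(df, sex)
        ns = table[table["row"] == "n"].iloc[0][
            ["very_young", "young", "intermediate", "old"]]
        total += int(ns.sum())
        # binary rows never exceed stratum n
        smoking = table[table["row"] == "smoking"].iloc[0]
        for g in ("very_young", "young", "intermediate", "old"):
            if smoking[g]:
                count = int(str(smoking[g]).split(" ")[0])
                assert count <= int(ns[g])
    assert total == len(df)


def test_characteristics_table_reflects_declining_smoking(small_truth):
    """The generator's smoking prevalence declines with age; the men's table
    shows it and the trend test calls it."""
    df = _analysis_frame(small_truth)
    table = characteristics_table(df, Sex.MALE)
    row = table[table["row"] == "smoking"].iloc[0]
    pcts = [float(str(row[g]).split("(")[1].rstrip(")"))
            for g in ("young", "intermediate", "old") if row[g]]
    assert pcts[0] > pcts[-1]
    assert row["p_trend"] < 0.05


def test_presentation_summary_anova_equals_t_squared(rng):
    """Two-category degenerate case: one-way ANOVA F equals t^2."""
    from scipy import stats
    a = rng.normal(size=40)
    b = rng.normal(loc=0.5, size=35)
    f, p_f = stats.f_oneway(a, b)
    t, p_t = stats.ttest_ind(a, b)
    assert f == pytest.approx(t ** 2, rel=1e-10)
    assert p_f == pytest.approx(p_t, rel=1e-10)

    df = pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(75)],
        "presentation": ["STEMI"] * 40 + ["SAP"] * 35,
        "ugrs_cad": np.r_[a, b] + 68.0,
        "familial_cad": rng.integers(0, 2, size=75).astype(float),
    })
    out = presentation_summary(df)
    assert out.loc[out["row"] == "ugrs_cad", "p_diff"].iloc[0] == pytest.approx(
        p_f, rel=1e-10)


def test_presentation_summary_published_familial_cad_gradient(rng):
    """Familial-CAD prevalence graded 32.7 -> 52.5% across presentations
    (published counts) gives chi-square p < 0.0001."""
    totals = presentation_totals()
    rows = []
    i = 0
    for pres, n in totals.items():
        k = PRESENTATION_FAMILIAL_CAD[pres]
        for j in range(n):
            rows.append({"subject_id": f"S{i}", "presentation": pres,
                         "familial_cad": 1.0 if j < k else 0.0})
            i += 1
    df = pd.DataFrame(rows)
    out = presentation_summary(df)
    fam = out[out["row"] == "familial_cad"].iloc[0]
    assert fam["p_diff"] < 0.0001
    assert fam["STEMI"].endswith("(32.7)")
    assert fam["SAP"].endswith("(52.4)") or fam["SAP"].endswith("(52.5)")


def test_derived_overall_summary_published_identities():
    """Pooling the published stratum summaries reproduces the whole-cohort
    figures: mean age 64, 28% women, 41% familial CAD."""
    pooled = derived_overall_summary(reference_strata())
    assert round(pooled["pooled_mean_age"]) == 64
    assert round(pooled["pct_women"]) == 28
    assert round(pooled["pct_familial_cad"]) == 41
    by_pres = familial_cad_by_presentation()
    assert by_pres["STEMI"] == pytest.approx(32.7, abs=0.05)
    # summed stratum counts give 268/511 = 52.45%; one printed digit
    assert by_pres["SAP"] == pytest.approx(52.5, abs=0.1)


def test_derived_overall_summary_single_stratum_identity():
    one = pd.DataFrame([{"sex": "male", "group": "young", "n": 50,
                         "mean_age": 48.0, "familial_cad_n": 20}])
    pooled = derived_overall_summary(one)
    assert pooled["pooled_mean_age"] == 48.0
    assert pooled["pct_women"] == 0.0
    assert pooled["pct_familial_cad"] == 40.0
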