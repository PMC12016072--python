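"""Cluster descriptives, the SES membership model, and hospitalization
outcomes, checked against closed-form and textbook computations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from careseq import (
    fit_membership_model,
    hospitalization_outcomes,
    orient_clusters,
    summarize_clusters,
)
from careseq.config import SES_FIELDS
from careseq.profiling import NonConvergenceWarning, ProfilingError


def _cohort_frame(n, **overrides):
    """Complete-SES patient frame with neutral defaults."""
    base = {
        "patient_id": [f"p{i}" for i in range(n)],
        "birth_year": [2004] * n,
        "sex": ["female"] * n,
        "dmp_enrolled": [False] * n,
        "comorbidity_autoimmune": [False] * n,
        "comorbidity_asthma": [False] * n,
        "comorbidity_psychological": [False] * n,
        "comorbidity_cardiovascular": [False] * n,
        "education_abitur": [False] * n,
        "university_degree": [False] * n,
        "job_type": ["specialist"] * n,
        "unemployed": [False] * n,
        "migration_history": [False] * n,
        "district_type": ["urban"] * n,
        "ses_missing": [False] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


def test_chi_square_matches_hand_formula_on_2x2_table():
    """Counts (20,10 / 10,20): X^2 = 60*(20*20-10*10)^2 / (30*30*30*30) = 6.666..."""
    n = 60
    cov = [True] * 20 + [False] * 10 + [True] * 10 + [False] * 20
    cluster = [0] * 30 + [1] * 30
    cohort = _cohort_frame(n, dmp_enrolled=cov)
    assignment = pd.Series(cluster, index=cohort["patient_id"])
    table = summarize_clusters(cohort, assignment, adherent_label=0)
    row = table[table["covariate"] == "dmp_enrolled"].iloc[0]
    expected_p = float(stats.chi2.sf(20.0 / 3.0, 1))
    assert row["p_value"] == pytest.approx(expected_p, rel=1e-10)
    assert row["cluster_0_adherent"] == pytest.approx(20 / 30)
    assert row["cluster_1"] == pytest.approx(10 / 30)


def test_identical_covariate_across_clusters_gives_p_near_one():
    n = 80
    cov = ([True] * 20 + [False] * 20) * 2
    cluster = [0] * 40 + [1] * 40
    cohort = _cohort_frame(n, education_abitur=cov)
    assignment = pd.Series(cluster, index=cohort["patient_id"])
    table = summarize_clusters(cohort, assignment, adherent_label=0)
    row = table[table["covariate"] == "education_abitur"].iloc[0]
    assert row["p_value"] == pytest.approx(1.0)


def test_single_level_covariate_is_skipped_with_note():
    cohort = _cohort_frame(20)
    assignment = pd.Series([0] * 10 + [1] * 10, index=cohort["patient_id"])
    table = summarize_clusters(cohort, assignment, adherent_label=0)
    row = table[table["covariate"] == "dmp_enrolled"].iloc[0]
    assert np.isnan(row["p_value"]) and "skipped" in row["note"]


def test_planted_share_appears_in_summary(small_tables):
    truth = small_tables["truth"].set_index("patient_id")["archetype"]
    cohort = small_tables["patients"]
    assignment = (truth == "adherent").astype(int).loc[cohort["patient_id"]]
    table = summarize_clusters(cohort, assignment, adherent_label=1)
    assert {"covariate", "overall", "p_value"} <= set(table.columns)
    # per-cluster patient proportions are probabilities
    num = table[["overall", "cluster_0", "cluster_1_adherent"]].to_numpy(float)
    assert ((num >= 0) & (num <= 1)).all()


def test_logistic_or_equals_cross_product_ratio_on_saturated_2x2():
    """Outcome/predictor table a=30 b=10 c=10 d=30 -> OR = 900/100 = 9."""
    n = 80
    pred = [True] * 40 + [False] * 40
    outcome = [1] * 30 + [0] * 10 + [1] * 10 + [0] * 30
    cohort = _cohort_frame(n, dmp_enrolled=pred)
    out = pd.Series(outcome, index=cohort["patient_id"], dtype=float)
    res = fit_membership_model(cohort, out, predictors=("dmp_enrolled",))
    assert res.converged
    assert res.table.loc["dmp_enrolled", "odds_ratio"] == pytest.approx(9.0, rel=1e-4)
    assert res.n_used == n and res.excluded_missing_ses == 0


def test_missing_ses_patients_are_excluded_and_counted():
    n = 60
    cohort = _cohort_frame(n, dmp_enrolled=[True, False] * 30)
    for f in SES_FIELDS:
        cohort[f] = cohort[f].astype(object)
    cohort.loc[:9, "education_abitur"] = pd.NA
    rng = np.random.default_rng(0)
    out = pd.Series(rng.integers(0, 2, n), index=cohort["patient_id"], dtype=float)
    res = fit_membership_model(cohort, out, predictors=("dmp_enrolled",))
    assert res.excluded_missing_ses == 10
    assert res.n_used == 50


def test_ci_bounds_bracket_odds_ratio(small_tables):
    cohort = small_tables["patients"]
    truth = small_tables["truth"].set_index("patient_id")["archetype"]
    out = (truth == "adherent").astype(float).loc[cohort["patient_id"]]
    res = fit_membership_model(cohort, out, predictors=("dmp_enrolled",))
    t = res.table
    assert ((t["ci_low"] <= t["odds_ratio"]) & (t["odds_ratio"] <= t["ci_high"])).all()
    assert (t["odds_ratio"] > 0).all()


def test_perfect_separation_reported_not_silent():
    n = 40
    pred = [True] * 20 + [False] * 20
    outcome = [1] * 20 + [0] * 20  # predictor separates outcome perfectly
    cohort = _cohort_frame(n, dmp_enrolled=pred)
    out = pd.Series(outcome, index=cohort["patient_id"], dtype=float)
    with pytest.warns(NonConvergenceWarning):
        res = fit_membership_model(cohort, out, predictors=("dmp_enrolled",))
    assert not res.converged
    assert res.diagnostic != ""
    assert res.table["odds_ratio"].isna().all()


def _hosp_table(ids, counts):
    rows = []
    for pid, c in zip(ids, counts):
        rows += [{"patient_id": pid, "date": "2018-06-01", "primary_t1dm": True}] * c
    return pd.DataFrame(rows, columns=["patient_id", "date", "primary_t1dm"])


def test_hospitalization_ratio_and_tests(rng):
    n = 400
    cohort = _cohort_frame(n)
    cluster = np.array([1] * 300 + [0] * 100)
    counts = np.where(cluster == 1, rng.poisson(1.11, n), rng.poisson(1.54, n))
    hosp = _hosp_table(cohort["patient_id"], counts)
    assignment = pd.Series(cluster, index=cohort["patient_id"])
    out = hospitalization_outcomes(cohort, hosp, assignment, adherent_label=1)
    mean_a = counts[cluster == 1].mean()
    mean_g = counts[cluster == 0].mean()
    assert out.mean_ratio == pytest.approx(mean_g / mean_a)
    t_expected = stats.ttest_ind(
        counts[cluster == 1], counts[cluster == 0], equal_var=False
    ).pvalue
    assert out.p_count == pytest.approx(t_expected)


def test_zero_hospitalizations_everywhere_is_flagged():
    cohort = _cohort_frame(20)
    hosp = _hosp_table([], [])
    assignment = pd.Series([0] * 10 + [1] * 10, index=cohort["patient_id"])
    out = hospitalization_outcomes(cohort, hosp, assignment, adherent_label=1)
    assert np.isnan(out.mean_ratio) and np.isnan(out.p_count)
    assert (out.table["mean_count"] == 0).all()
    assert "undefined" in out.note


def test_identical_rates_give_ratio_near_one(rng):
    n = 2000
    cohort = _cohort_frame(n)
    cluster = np.array([0, 1] * (n // 2))
    counts = rng.poisson(1.2, n)
    hosp = _hosp_table(cohort["patient_id"], counts)
    assignment = pd.Series(cluster, index=cohort["patient_id"])
    out = hospitalization_outcomes(cohort, hosp, assignment, adherent_label=1)
    assert out.mean_ratio == pytest.approx(1.0, abs=0.15)


def test_empty_cluster_is_an_error():
    cohort = _cohort_frame(10)
    assignment = pd.Series([0] * 10, index=cohort["patient_id"])
    with pytest.raises(ProfilingError):
        hospitalization_outcomes(cohort, _hosp_table([], []), assignment, 0)


def test_orientation_picks_higher_hba1c_cluster():
    wide = pd.DataFrame(
        [["HB"] * 12, ["H"] * 12, ["N"] * 12, ["B"] * 12],
        index=pd.Index(["a", "b", "c", "d"], name="patient_id"),
    )
    assignment = pd.Series([5, 5, 9, 9], index=["a", "b", "c", "d"])
    assert orient_clusters(wide, assignment) == 5
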