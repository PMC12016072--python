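"""Cluster characterization: descriptive tests, the SES membership model,
and hospitalization outcomes.

Covariates are compared between clusters with chi-square tests (binary),
Kruskal-Wallis tests (ordered multi-category: birth year, job type,
district type) and Welch t-tests (continuous counts), at a 5% significance
level with no multiple-testing correction. The association between SES and
membership in the guideline-adherent cluster is quantified with a logistic
regression reported as odds ratios with Wald 95% confidence intervals;
patients with missing parental SES are kept in the clustering and the
descriptive table but excluded from the regression.

PAM's cluster labels are arbitrary, so clusters are oriented post hoc from
care content: the cluster with the higher mean number of HbA1c quarters is
the "guideline-adherent" one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import SES_FIELDS


class ProfilingError(ValueError):
    pass


#: Table 2-style default predictor set of the membership model.
DEFAULT_PREDICTORS = (
    "birth_year_centered",
    "dmp_enrolled",
    "comorbidity_autoimmune",
    "education_abitur",
    "unemployed",
)

#: covariate -> test kind used in the cluster summary
COVARIATE_TESTS = {
    "birth_year": "kruskal_wallis",
    "sex": "chi_square",
    "dmp_enrolled": "chi_square",
    "comorbidity_autoimmune": "chi_square",
    "comorbidity_asthma": "chi_square",
    "comorbidity_psychological": "chi_square",
    "comorbidity_cardiovascular": "chi_square",
    "ses_missing": "chi_square",
    "education_abitur": "chi_square",
    "university_degree": "chi_square",
    "job_type": "kruskal_wallis",
    "migration_history": "chi_square",
    "unemployed": "chi_square",
    "district_type": "kruskal_wallis",
}

_JOB_ORDER = ["unskilled", "specialist", "complex_specialist", "highly_complex"]
_DISTRICT_ORDER = ["large_city", "urban", "rural_agglomeration", "sparse"]


def orient_clusters(diagnostics_wide: pd.DataFrame, assignment: pd.Series) -> int:
    """Label of the guideline-adherent cluster.

    The cluster whose members average more quarters with an HbA1c
    measurement (state H or HB) is taken as guideline-adherent.
    """
    hba1c_quarters = diagnostics_wide.apply(
        lambda row: sum("H" in s for s in row), axis=1
    )
    means = hba1c_quarters.groupby(assignment.loc[diagnostics_wide.index]).mean()
    return int(means.idxmax())


def _chi_square(values: pd.Series, groups: pd.Series) -> float:
    table = pd.crosstab(values, groups)
    if table.shape[0] < 2 or table.shape[1] < 2:
        return float("nan")
    stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(p)


def _kruskal(values: pd.Series, groups: pd.Series, order: list | None) -> float:
    if order is not None:
        rank = {v: i for i, v in enumerate(order)}
        values = values.map(rank)
    samples = [v.dropna().to_numpy(dtype=float) for _, v in values.groupby(groups)]
    samples = [s for s in samples if len(s)]
    if len(samples) < 2:
        return float("nan")
    try:
        return float(stats.kruskal(*samples).pvalue)
    except ValueError:  # all values identical
        return float("nan")


def summarize_clusters(
    cohort: pd.DataFrame,
    assignment: pd.Series,
    adherent_label: int | None = None,
) -> pd.DataFrame:
    """Per-cluster descriptive table with between-cluster test p-values.

    One row per covariate level: overall and per-cluster proportions (or
    means), the test applied and its p-value. Missing SES is reported as
    its own binary row; missing values never drop a patient from this
    table.
    """
    assignment = assignment.loc[cohort["patient_id"]]
    groups = assignment.to_numpy()
    labels = sorted(np.unique(groups))
    rows = []

    def cluster_cols(series: pd.Series, reducer) -> dict:
        out = {"overall": reducer(series)}
        for lab in labels:
            name = f"cluster_{lab}" + ("_adherent" if lab == adherent_label else "")
            out[name] = reducer(series[groups == lab])
        return out

    for cov, test in COVARIATE_TESTS.items():
        if cov not in cohort.columns:
            continue
        series = cohort[cov].reset_index(drop=True)
        gser = pd.Series(groups)
        if test == "chi_square":
            p = _chi_square(series.fillna("missing"), gser)
        else:
            order = {"job_type": _JOB_ORDER, "district_type": _DISTRICT_ORDER}.get(cov)
            p = _kruskal(series, gser, order)
        nlevels = series.dropna().nunique()
        if nlevels < 2:
            p, note = float("nan"), "single level, test skipped"
        else:
            note = ""
        levels = sorted(series.dropna().unique(), key=str)
        binary_like = set(map(str, levels)) <= {"True", "False"} or cov == "sex"
        if binary_like:
            target = True if cov != "sex" else "female"
            rows.append(
                {"covariate": cov, "level": str(target), "test": test, "p_value": p,
                 "note": note}
                | cluster_cols(series, lambda s: float((s == target).mean()))
            )
        else:
            for lev in levels:
                rows.append(
                    {"covariate": cov, "level": str(lev), "test": test, "p_value": p,
                     "note": note}
                    | cluster_cols(series, lambda s, lev=lev: float((s == lev).mean()))
                )
    return pd.DataFrame(rows)


class NonConvergenceWarning(UserWarning):
    """The membership model did not reach a valid maximum-likelihood fit."""


@dataclass(frozen=True)
class RegressionResult:
    """Odds ratios with Wald 95% CIs from the membership logistic model."""

    table: pd.DataFrame  # index: predictor; columns: odds_ratio, ci_low, ci_high, p_value
    n_used: int
    excluded_missing_ses: int
    converged: bool
    diagnostic: str = ""


def fit_membership_model(
    cohort: pd.DataFrame,
    outcome: pd.Series,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
) -> RegressionResult:
    """Maximum-likelihood logistic fit of adherent-cluster membership.

    ``outcome`` is a 0/1 series indexed by patient_id (1 = adherent-type
    cluster). Birth year enters mean-centered. Patients with any missing
    parental SES field are excluded (their count is reported). CIs are Wald
    intervals on the log-odds scale, exponentiated to the OR scale.
    """
    df = cohort.set_index("patient_id")
    ses_cols = [c for c in SES_FIELDS if c in df.columns]
    complete = ~df[ses_cols].isna().any(axis=1)
    excluded = int((~complete).sum())
    df = df[complete]
    y = outcome.loc[df.index].astype(float)

    X = pd.DataFrame(index=df.index)
    for name in predictors:
        if name == "birth_year_centered":
            X[name] = df["birth_year"].astype(float) - df["birth_year"].astype(float).mean()
        else:
            X[name] = df[name].astype(float)
    X = sm.add_constant(X, prepend=True)

    def _failed(diagnostic: str) -> RegressionResult:
        warnings.warn(f"membership model not converged: {diagnostic}",
                      NonConvergenceWarning, stacklevel=3)
        empty = pd.DataFrame(
            np.nan, index=X.columns,
            columns=["odds_ratio", "ci_low", "ci_high", "p_value"],
        )
        return RegressionResult(table=empty, n_used=int(len(df)),
                                excluded_missing_ses=excluded, converged=False,
                                diagnostic=diagnostic)

    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        warnings.simplefilter("ignore", category=sm.tools.sm_exceptions.ConvergenceWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=False)
            converged = bool(fit.mle_retvals["converged"])
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning,
                np.linalg.LinAlgError) as exc:
            return _failed(f"perfect or quasi separation: {exc}")
    if not converged or not np.isfinite(fit.params).all():
        return _failed("maximum-likelihood optimization did not converge")

    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "odds_ratio": np.exp(fit.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "p_value": fit.pvalues,
        }
    )
    return RegressionResult(
        table=table, n_used=int(len(df)), excluded_missing_ses=excluded, converged=converged
    )


@dataclass(frozen=True)
class OutcomeSummary:
    """Hospitalization outcomes per cluster."""

    table: pd.DataFrame  # per cluster: n, prop_any_hospitalization, mean_count
    p_any: float
    p_count: float
    mean_ratio: float  # gaps mean / adherent mean (NaN if undefined)
    note: str = ""


def hospitalization_outcomes(
    cohort: pd.DataFrame,
    hospitalizations: pd.DataFrame,
    assignment: pd.Series,
    adherent_label: int,
) -> OutcomeSummary:
    """Compare T1DM-primary hospitalization burden between clusters.

    The binary any-hospitalization outcome is tested with a chi-square
    test, the per-patient count with a Welch t-test; the ratio of mean
    counts (care-with-gaps over guideline-adherent) is reported alongside.
    """
    ids = cohort["patient_id"]
    a = assignment.loc[ids]
    labels = sorted(a.unique())
    if len(labels) < 2:
        raise ProfilingError("need at least two clusters")
    hosp = hospitalizations
    if "primary_t1dm" in hosp.columns:
        hosp = hosp[hosp["primary_t1dm"].astype(bool)]
    counts = hosp.groupby("patient_id").size().reindex(ids, fill_value=0)
    counts.index = ids

    per_cluster = []
    samples = {}
    for lab in labels:
        c = counts[a.to_numpy() == lab]
        if len(c) == 0:
            raise ProfilingError(f"cluster {lab} is empty")
        samples[lab] = c
        per_cluster.append(
            {
                "cluster": lab,
                "adherent": lab == adherent_label,
                "n": int(len(c)),
                "prop_any_hospitalization": float((c > 0).mean()),
                "mean_count": float(c.mean()),
            }
        )
    table = pd.DataFrame(per_cluster)

    note = ""
    any_flag = (counts > 0).astype(int)
    if any_flag.nunique() < 2:
        p_any = float("nan")
        note = "no variation in hospitalization outcomes"
    else:
        p_any = _chi_square(any_flag.reset_index(drop=True), pd.Series(a.to_numpy()))
    if counts.sum() == 0:
        p_count, ratio = float("nan"), float("nan")
        note = "zero hospitalizations everywhere; ratio undefined"
    else:
        two = [samples[lab].to_numpy(dtype=float) for lab in labels]
        p_count = float(stats.ttest_ind(*two[:2], equal_var=False).pvalue)
        adherent_mean = table.loc[table["adherent"], "mean_count"].iloc[0]
        gaps_mean = table.loc[~table["adherent"], "mean_count"].iloc[0]
        ratio = float(gaps_mean / adherent_mean) if adherent_mean > 0 else float("nan")
        if adherent_mean == 0:
            note = "adherent-cluster mean is zero; ratio undefined"
    return OutcomeSummary(table=table, p_any=p_any, p_count=p_count, mean_ratio=ratio,
                          note=note)
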