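"""Generator: determinism, planted structure, and statistical calibration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from pandas.testing import assert_frame_equal
from scipy.special import expit

from careseq import (
    ConfigurationError,
    GeneratorConfig,
    generate_cohort,
    generate_patients,
    read_fixture,
    write_fixture,
)
from careseq.config import DEFAULT_SES_LOGIT, SES_FIELDS


def test_identical_config_and_seed_reproduce_tables(small_config, small_tables):
    again = generate_cohort(small_config)
    for name, df in small_tables.items():
        assert_frame_equal(df, again[name])


def test_different_seed_changes_output(small_config, small_tables):
    other = generate_cohort(dataclasses.replace(small_config, seed=small_config.seed + 1))
    assert not small_tables["events"].equals(other["events"])


def test_mixture_proportion_controls_archetype_share():
    """n=900 at mixture 0.75 lands within the binomial 99% band around 675."""
    cfg = GeneratorConfig(n_patients=900, mixture_proportion_adherent=0.75, seed=11)
    _, truth = generate_patients(cfg)
    n_adherent = int((truth["archetype"] == "adherent").sum())
    assert abs(n_adherent - 675) <= 35


def test_degenerate_mixture_all_adherent():
    cfg = GeneratorConfig(n_patients=200, mixture_proportion_adherent=1.0, seed=5)
    tables = generate_cohort(cfg)
    assert (tables["truth"]["archetype"] == "adherent").all()


def test_zero_hospitalization_rates_emit_no_rows():
    cfg = GeneratorConfig(n_patients=150, hosp_rate_adherent=0.0, hosp_rate_gaps=0.0, seed=2)
    tables = generate_cohort(cfg)
    assert len(tables["hospitalizations"]) == 0


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_patients": 0},
        {"mixture_proportion_adherent": 0.0},
        {"mixture_proportion_adherent": 1.2},
        {"ses_missing_rate": -0.1},
        {"hosp_rate_adherent": -1.0},
        {"observation_window": ("2017-02-01", "2019-12-31")},
        {"observation_window": ("2019-12-31", "2017-01-01")},
    ],
)
def test_invalid_configuration_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        GeneratorConfig(**kwargs)


def test_fixture_round_trip(tmp_path, small_config, small_tables):
    write_fixture(small_tables, tmp_path, small_config)
    back = read_fixture(tmp_path)
    for name, df in small_tables.items():
        assert_frame_equal(
            df.reset_index(drop=True), back[name], check_dtype=False
        )


def test_fixture_write_is_byte_deterministic(tmp_path, small_config, small_tables):
    p1 = write_fixture(small_tables, tmp_path / "a", small_config)
    p2 = write_fixture(small_tables, tmp_path / "b", small_config)
    for name in p1:
        assert p1[name].read_bytes() == p2[name].read_bytes()


def test_empty_tables_write_header_only_csvs(tmp_path, small_tables):
    empty = {k: v.iloc[0:0] for k, v in small_tables.items()}
    paths = write_fixture(empty, tmp_path)
    for name, path in paths.items():
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and "patient_id" in lines[0]


def test_per_quarter_event_rates_recovered_at_large_n():
    """Empirical HbA1c quarter frequency within 3 SE per archetype (n=5000)."""
    cfg = GeneratorConfig(n_patients=5000, seed=7)
    tables = generate_cohort(cfg)
    truth = tables["truth"].set_index("patient_id")["archetype"]
    ev = tables["events"]
    hba1c = ev[ev["event_code"] == "HBA1C"].groupby("patient_id").size()
    for archetype, p in (("adherent", cfg.rates_adherent.hba1c),
                         ("gaps", cfg.rates_gaps.hba1c)):
        ids = truth.index[truth == archetype]
        n_quarters = 12 * len(ids)
        observed = hba1c.reindex(ids, fill_value=0).sum() / n_quarters
        se = np.sqrt(p * (1 - p) / n_quarters)
        assert abs(observed - p) <= 3 * se


def test_ses_missingness_rate_recovered():
    cfg = GeneratorConfig(n_patients=5000, seed=9)
    patients, _ = generate_patients(cfg)
    frac = patients["ses_missing"].mean()
    se = np.sqrt(0.16 * 0.84 / 5000)
    assert abs(frac - cfg.ses_missing_rate) <= 3 * se
    missing_block = patients.loc[patients["ses_missing"], list(SES_FIELDS)]
    assert missing_block.isna().all().all()


def test_archetype_follows_ses_logistic_model():
    """Planted log-odds signs are recovered by refitting in >=95% of replicates."""
    slopes = {k: v for k, v in DEFAULT_SES_LOGIT.items()}
    hits = {k: 0 for k in slopes}
    n_rep = 200
    for rep in range(n_rep):
        cfg = GeneratorConfig(n_patients=900, seed=10_000 + rep)
        patients, truth = generate_patients(cfg)
        y = (truth["archetype"] == "adherent").astype(float)
        X = pd.DataFrame(
            {
                "birth_year_centered": patients["birth_year"]
                - patients["birth_year"].mean(),
                "dmp_enrolled": patients["dmp_enrolled"].astype(float),
                "comorbidity_autoimmune": patients["comorbidity_autoimmune"].astype(float),
                # regress on the pre-missingness covariates via the truth draw
                "education_abitur": patients["education_abitur"].map(
                    {True: 1.0, False: 0.0}
                ),
                "unemployed": patients["unemployed"].map({True: 1.0, False: 0.0}),
            }
        )
        keep = X.notna().all(axis=1)
        fit = sm.Logit(y[keep], sm.add_constant(X[keep])).fit(disp=False)
        for k in slopes:
            if np.sign(fit.params[k]) == np.sign(slopes[k]):
                hits[k] += 1
    for k, h in hits.items():
        assert h / n_rep >= 0.95, f"sign of {k} recovered in only {h}/{n_rep}"


def test_intercept_calibration_hits_target_mixture():
    """Mean archetype probability matches the configured mixture for several targets."""
    for target in (0.3, 0.5, 0.75, 0.9):
        cfg = GeneratorConfig(n_patients=4000, mixture_proportion_adherent=target, seed=21)
        _, truth = generate_patients(cfg)
        share = (truth["archetype"] == "adherent").mean()
        se = np.sqrt(target * (1 - target) / 4000)
        assert abs(share - target) <= 4 * se
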