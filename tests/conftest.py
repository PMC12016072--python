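from datetime import date

import numpy as np
import pandas as pd
import pytest

from careseq import GeneratorConfig, generate_cohort

WINDOW = (date(2017, 1, 1), date(2019, 12, 31))


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_patients=120, seed=3)


@pytest.fixture(scope="session")
def small_tables(small_config):
    return generate_cohort(small_config)


def make_events(rows):
    """Build an events table from (patient_id, date, code, quantity, setting) tuples."""
    return pd.DataFrame(
        rows, columns=["patient_id", "date", "event_code", "quantity", "setting"]
    )


def make_diagnoses(rows):
    return pd.DataFrame(rows, columns=["patient_id", "date", "setting", "code"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
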