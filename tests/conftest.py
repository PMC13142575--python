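import pandas as pd
import pytest

from ehrgenrisk.phenotyping import default_codeset
from ehrgenrisk.pipeline import build_analysis_cohort
from ehrgenrisk.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_participants=800, seed=7)


@pytest.fixture(scope="session")
def small_cohort_tables(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_analysis_cohort(small_cohort_tables):
    cohort, phenotypes, exclusions = build_analysis_cohort(
        small_cohort_tables["participants"],
        small_cohort_tables["billing"],
        default_codeset(),
    )
    return cohort


def make_billing(rows):
    """rows: iterable of (pid, code, system, kind, age_days)."""
    return pd.DataFrame(
        rows, columns=["participant_id", "code", "code_system", "record_kind", "age_days"]
    )
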