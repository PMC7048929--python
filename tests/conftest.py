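import pathlib

import pandas as pd
import pytest

from situscan.pipeline import run_on_bundle
from situscan.synthetic import CohortSpec, generate, make_table1_fixture


@pytest.fixture(scope="session")
def table1_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("table1")
    return make_table1_fixture(out)


@pytest.fixture(scope="session")
def table1_result(table1_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("table1_run")
    return run_on_bundle(table1_bundle, out)


@pytest.fixture(scope="session")
def cohort_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    return generate(CohortSpec(seed=7), out)


@pytest.fixture(scope="session")
def cohort_truth(cohort_bundle):
    return pd.read_csv(cohort_bundle["truth"], sep="\t")


@pytest.fixture(scope="session")
def cohort_result(cohort_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort_run")
    return run_on_bundle(cohort_bundle, out)


def make_subjects(rows):
    """rows: (subject_id, group, sex, ehi, forced_switch) tuples."""
    return pd.DataFrame(
        [
            {
                "subject_id": sid, "group": group, "sex": sex, "ehi": ehi,
                "forced_switch": fs, "daily_wet_cough": "no", "chd": False,
            }
            for sid, group, sex, ehi, fs in rows
        ]
    )
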