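import datetime as dt

import numpy as np
import pytest

from emrisk.cohort import PatientHistory
from emrisk.records import DiagnosticRecord
from emrisk.synthetic import SyntheticConfig, generate_synthetic_emr


def rec(pid, date, code, code5=None):
    return DiagnosticRecord(pid, date, code, code5)


@pytest.fixture
def toy_histories():
    """Two labeled patients over a three-code vocabulary."""
    h1 = PatientHistory(
        "P0000000001",
        "case",
        (
            rec("P0000000001", "2001-01-01", "001.00", "00100"),
            rec("P0000000001", "2001-02-01", "002.00", "00200"),
        ),
        censor_date=dt.date(2002, 1, 1),
    )
    h2 = PatientHistory(
        "P0000000002",
        "control",
        (rec("P0000000002", "2003-05-05", "002.00", "00200"),),
    )
    return [h1, h2]


@pytest.fixture(scope="session")
def small_emr(tmp_path_factory):
    """A small generated EMR cohort shared across tests (read-only)."""
    cfg = SyntheticConfig(
        n_cases=40,
        n_controls=40,
        vocab_size=60,
        k_themes=3,
        n_risk_themes=1,
        noise_rate=0.05,
        seed=11,
    )
    out = tmp_path_factory.mktemp("emr")
    paths = generate_synthetic_emr(cfg, out)
    return cfg, paths


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
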