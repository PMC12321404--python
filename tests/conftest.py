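import pandas as pd
import pytest

from methet.synthetic import SyntheticCohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared across tests (deterministic)."""
    cfg = SyntheticCohortConfig(n_patients=12, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The default-condition cohort (52 patients)."""
    cfg = SyntheticCohortConfig()
    return generate_cohort(cfg, seed=5)


def make_core_rows(patient="P1", site="bone", block="B1", core="C1",
                   ar=150, nkx=120, syp=0, insm1=5, ki67=10.0):
    rows = []
    for marker, value in (("AR", ar), ("NKX3.1", nkx), ("SYP", syp),
                          ("INSM1", insm1), ("Ki67", ki67)):
        rows.append({"patient_id": patient, "site": site, "block_id": block,
                     "core_id": core, "marker": marker, "value": value})
    return rows


@pytest.fixture
def one_row_table():
    return pd.DataFrame([{"patient_id": "P1", "site": "bone", "block_id": "B1",
                          "core_id": "C1", "marker": "AR", "value": 150}])
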