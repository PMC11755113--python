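import numpy as np
import pandas as pd
import pytest

from covpattern import PhantomSpec, make_phantom_cohort


@pytest.fixture(scope="session")
def small_phantom():
    """Desk-scale strong-effect cohort shared across tests (16^3 grid)."""
    spec = PhantomSpec(shape=(16, 16, 16), n_hc=6, n_pd=12, seed=42)
    return make_phantom_cohort(spec)


@pytest.fixture(scope="session")
def default_phantom():
    """Default study-condition cohort: 32^3 grid, 10 controls / 34 patients."""
    return make_phantom_cohort(PhantomSpec(seed=7))


@pytest.fixture()
def toy_cognition_table():
    """Two reference subjects and one patient, one test per domain plus one
    extra memory test; hand-checkable z-scores."""
    rows = []
    raw = {
        "HC1": {"VAT": 10, "MoCA_MIS": 10, "SDMT": 40, "Stroop_C_B": 30, "JOLO": 20},
        "HC2": {"VAT": 12, "MoCA_MIS": 14, "SDMT": 44, "Stroop_C_B": 34, "JOLO": 24},
        "PD1": {"VAT": 9, "MoCA_MIS": 12, "SDMT": 38, "Stroop_C_B": 38, "JOLO": 18},
    }
    for sid, tests in raw.items():
        for tid, x in tests.items():
            rows.append({"subject_id": sid, "test_id": tid, "raw_score": float(x)})
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
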