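import numpy as np
import pandas as pd
import pytest

from ensemblemark import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    """A desk-scale two-site cohort used across the unit suite."""
    return CohortSpec(n_sites=2, patients_per_site=(40, 40), n_genes=30, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def toy_clinical(times, events, stages=None, sites=None):
    """Build a minimal clinical table from parallel sequences."""
    n = len(times)
    return pd.DataFrame({
        "patient_id": [f"p{i:02d}" for i in range(n)],
        "site": sites or ["site01"] * n,
        "stage": stages or ["IA"] * n,
        "time_months": list(times),
        "event": list(events),
    })


def toy_calls(calls):
    return pd.DataFrame({
        "patient_id": [f"p{i:02d}" for i in range(len(calls))],
        "call": list(calls),
    })
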