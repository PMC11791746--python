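import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from prolifmeta.dataio import CLINICAL_COLUMNS, ExpressionDataset
from prolifmeta.syndata import SimulationConfig, simulate_cohort_collection

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_clinical(samples, **overrides):
    """Minimal valid clinical table for hand-built fixture datasets."""
    n = len(samples)
    base = {
        "er": ["positive"] * n,
        "pr": ["positive"] * n,
        "her2": ["negative"] * n,
        "grade": ["2"] * n,
        "node": ["negative"] * n,
        "size": ["T1"] * n,
        "subtype": ["unknown"] * n,
        "time_months": [12.0] * n,
        "event": [0] * n,
        "endpoint": ["RFS"] * n,
        "treated": ["no"] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base, index=pd.Index(samples, name="sample_id"))[
        list(CLINICAL_COLUMNS)
    ]


def make_dataset(values: pd.DataFrame, cohort_id="TEST", **clinical_overrides):
    return ExpressionDataset(
        cohort_id=cohort_id,
        values=values,
        clinical=make_clinical(list(values.columns), **clinical_overrides),
    )


@pytest.fixture(scope="session")
def small_collection():
    cfg = SimulationConfig(
        n_cohorts=3, samples_per_cohort=80, n_genes=200,
        n_proliferation_genes=30, seed=11,
    )
    return simulate_cohort_collection(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
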