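import pandas as pd
import pytest
from hypothesis import settings

from anc_equity import SyntheticConfig, generate_survey, study_dimensions, table1_fixture

settings.register_profile("det", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def dims():
    return study_dimensions()


@pytest.fixture(scope="session")
def table1():
    """(grouped published subgroup estimates, national average)."""
    return table1_fixture()


@pytest.fixture(scope="session")
def default_survey():
    """One default-config synthetic survey (~8,568 women) with its truth."""
    return generate_survey(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def large_survey():
    """A larger synthetic survey (~20k women) for recovery-style checks."""
    cfg = SyntheticConfig(seed=7, n_clusters_per_stratum=20, n_women_per_cluster=28)
    return generate_survey(cfg)


@pytest.fixture()
def tiny_records():
    """Three women, one subgroup, hand-checkable weighted prevalence."""
    return pd.DataFrame({
        "anc4": [1, 0, 1],
        "weight": [2.0, 1.0, 1.0],
        "stratum_id": ["s1", "s1", "s1"],
        "cluster_id": [1, 1, 2],
        "residence": ["Rural", "Rural", "Rural"],
    })
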