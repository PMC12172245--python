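import numpy as np
import pandas as pd
import pytest

from coopbattery import econ_models as em
from coopbattery import synthetic_cohort as sc


@pytest.fixture(scope="session")
def grid() -> pd.DataFrame:
    return em.jpe_grid()


@pytest.fixture(scope="session")
def registry():
    return em.model_registry()


@pytest.fixture(scope="session")
def small_cohort():
    """A 6+6 cohort, enough to exercise every task record."""
    cfg = sc.CohortConfig(
        group_a=sc.GroupSpec(label="BPD", n=6, dissociality_mean=27.0),
        group_b=sc.GroupSpec(label="HC", n=6, dissociality_mean=20.0),
        seed=123,
    )
    return sc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The full 35 + 50 study-scale cohort."""
    return sc.generate_cohort(sc.DEFAULT_CONFIG)


@pytest.fixture(scope="session")
def default_trials(default_cohort) -> pd.DataFrame:
    return sc.trials_frame(default_cohort)
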