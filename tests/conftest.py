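import numpy as np
import pandas as pd
import pytest

from mocasim import load_joint_table


@pytest.fixture(scope="session")
def table():
    """The packaged joint distribution of the Italian 55-89 population."""
    return load_joint_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230101)


@pytest.fixture()
def toy_cohort():
    """Four-individual cohort with hand-checkable screening metrics."""
    return pd.DataFrame(
        {
            "sex": ["female"] * 4,
            "age": [60.0, 61.0, 62.0, 63.0],
            "age_low": [60] * 4,
            "age_high": [64] * 4,
            "edu_years": [8] * 4,
            "status": ["MCI", "MCI", "healthy", "healthy"],
            "raw_score": [10.0, 20.0, 25.0, 28.0],
        }
    )
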