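import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from trajerp import GenerativeConfig, generate_session
from trajerp.stats import CONDITION_ORDER


@pytest.fixture(scope="session")
def small_plan():
    return generate_session(per_condition=8, red_dot_total=4, seed=7)


@pytest.fixture(scope="session")
def noiseless_config():
    """Generator with every random component switched off."""
    return GenerativeConfig(
        n_subjects=1,
        trials_per_condition=8,
        red_dot_total=4,
        subject_sd_p1=0.0,
        subject_sd_n170=0.0,
        subject_sd_n2pc=0.0,
        subject_sd_n170_expectation=0.0,
        subject_sd_n170_cueing=0.0,
        subject_sd_n2pc_expectation=0.0,
        noise_white_sd=0.0,
        noise_pink_scale=0.0,
        blink_rate=0.0,
        seed=7,
    )


def make_cell_matrix(values: np.ndarray) -> pd.DataFrame:
    """Wrap an (n_subjects, 4) array as a condition cell matrix."""
    values = np.asarray(values, float)
    return pd.DataFrame(
        values,
        columns=list(CONDITION_ORDER),
        index=[f"S{i}" for i in range(values.shape[0])],
    )
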