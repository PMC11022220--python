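import numpy as np
import pandas as pd
import pytest

from evdassess import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One reference cohort at the default conditions, shared across tests."""
    return generate_cohort(CohortConfig(seed=2019))


@pytest.fixture(scope="session")
def default_measures(default_cohort):
    from evdassess import score_evd_trials

    return score_evd_trials(default_cohort.evd_trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_smr_trials(rows):
    """Build a same/different trial table from (pid, pair, truth, response, rt) tuples."""
    return pd.DataFrame(
        rows, columns=["participant_id", "pair_id", "truth", "response", "rt_s"]
    )
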