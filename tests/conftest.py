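import numpy as np
import pandas as pd
import pytest

from gnurture import simcohort
from gnurture.cli import analysis_frame


@pytest.fixture(scope="session")
def small_sim():
    """A 300-family cohort under default study conditions."""
    return simcohort.simulate_cohort(
        simcohort.SimulationConfig(n_families=300, seed=42)
    )


@pytest.fixture(scope="session")
def small_frame(small_sim):
    """Person-wave analysis frame (SES design + scores + PCs) for small_sim."""
    frame, blocks = analysis_frame(small_sim, k_pcs=4)
    return frame, blocks


@pytest.fixture(scope="session")
def truth_frame(small_sim):
    """Cohort rows merged with ground-truth standardized scores."""
    tp = small_sim.truth.persons.set_index("person_id")
    return small_sim.cohort.merge(
        tp[["z_u", "z_ses", "u_true", "ses_latent"]],
        left_on="person_id",
        right_index=True,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
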