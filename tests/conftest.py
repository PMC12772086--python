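import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim_config():
    from bst import SimConfig

    return SimConfig(n_dogs=800, ehr_n_dogs=1500, n_breeds=12, seed=42)


@pytest.fixture(scope="session")
def scored_cohort(small_sim_config):
    """A scored (but unfiltered) questionnaire cohort shared across tests."""
    from bst import generate_questionnaire_cohort, score_cohort

    raw, truth = generate_questionnaire_cohort(small_sim_config)
    scored = score_cohort(raw)
    scored["sex_male"] = (scored["sex"] == "male").astype(float)
    scored["neutered"] = (scored["neuter"] == "neutered").astype(float)
    return scored, truth
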