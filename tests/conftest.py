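import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from socionorm import SimulationConfig, simulate_study
from socionorm.likert_norms import fit_latent_means
from socionorm.synthetic_data import with_bad_actors

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_small():
    """Clean study at the reference conditions: 100 items, 60 attentive
    participants, participant shift SD 0.5."""
    return simulate_study(
        SimulationConfig(n_items=100, n_participants=60, seed=20)
    )


@pytest.fixture(scope="session")
def study_bad_actors():
    """60 participants with 5 planted actors of each bad-actor type."""
    cfg = with_bad_actors(
        SimulationConfig(n_items=100, n_participants=60, seed=11), 5
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def study_recovery():
    """Large attentive sample for parameter-recovery checks."""
    return simulate_study(
        SimulationConfig(n_items=100, n_participants=200, seed=5)
    )


@pytest.fixture(scope="session")
def gender_clmm(study_small):
    """Latent-mean fit for the gender dimension of the reference study."""
    real = study_small.design.real_items
    ratings = study_small.ratings[study_small.ratings.item_id.isin(real)]
    return fit_latent_means(ratings, "gender")


def make_ratings(rows):
    """Build a ratings frame from (participant, item, dimension, value)
    tuples; value None encodes UNKNOWN."""
    df = pd.DataFrame(
        rows, columns=["participant_id", "item_id", "dimension", "value"]
    )
    df["value"] = df["value"].astype("Int64")
    df["presentation_order"] = range(len(df))
    return df
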