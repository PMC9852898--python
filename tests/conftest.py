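import numpy as np
import pandas as pd
import pytest

from nwlchoice.synthetic import StudyConfig, simulate_study
from nwlchoice.trajectory import compute_trial_metrics


@pytest.fixture(scope="session")
def small_study():
    """Six-participant synthetic study with default contamination."""
    return simulate_study(StudyConfig(n_participants=6, rng_seed=11))


@pytest.fixture(scope="session")
def small_metrics(small_study):
    return compute_trial_metrics(small_study.trials, small_study.paths)


@pytest.fixture(scope="session")
def image_table():
    from nwlchoice._rng import rng_for
    from nwlchoice.synthetic import make_image_table

    return make_image_table(rng_for(0, "images"))


@pytest.fixture(scope="session")
def inventories(image_table):
    from nwlchoice.stimuli import build_inventories

    return build_inventories(image_table)
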