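import numpy as np
import pandas as pd
import pytest

from epichron import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_cohort():
    """40+40 subjects, one closing / one opening / null features."""
    spec = syn.SyntheticSpec(
        n_per_sex=40, age_range=(22, 90), seed=7, nb_dispersion=0.1,
        clusters=(
            syn.make_shape("down", 30, effect=2.0, age_range=(22, 90), baseline=6.0),
            syn.make_shape("up_late", 30, effect=2.0, age_range=(22, 90),
                           breakpoints=(60,), baseline=6.0),
            syn.make_shape("null", 40, baseline=6.0),
            # strong invariant features: benchmark-peak candidates
            syn.make_shape("null", 60, baseline=8.5),
        ))
    return syn.simulate_cohort(spec)


@pytest.fixture
def toy_counts():
    return pd.DataFrame(
        [[100, 210, 95], [50, 95, 52], [200, 420, 180], [10, 22, 9], [5, 8, 6]],
        index=[f"g{i}" for i in range(5)], columns=["a", "b", "c"])
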