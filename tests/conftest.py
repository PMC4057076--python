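import numpy as np
import pandas as pd
import pytest

import ruletrait as rt
from ruletrait.rules import Condition, Rule


@pytest.fixture(scope="session")
def latent_items():
    """Ten 2PL items with mixed signs, |a| in [1, 2.5], b in [-2, 2]."""
    rng = np.random.default_rng(7)
    a = rng.uniform(1.0, 2.5, 10) * rng.choice([-1, 1], 10)
    b = rng.uniform(-2.0, 2.0, 10)
    return tuple(zip(a.tolist(), b.tolist()))


@pytest.fixture(scope="session")
def small_latent_cohort(latent_items):
    cfg = rt.LatentGenConfig(
        n_subjects=300, item_params=latent_items, link=(0.0, 2.0), seed=11
    )
    return rt.sample_latent_cohort(cfg)


@pytest.fixture()
def toy_marker_table():
    """Four subjects, two numeric markers, hand-checkable."""
    df = pd.DataFrame(
        {
            "age": [5.0, 12.0, 9.0, 15.0],
            "fpir": [100.0, np.nan, 60.0, 42.0],
            "outcome": [0, 1, 0, 1],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return rt.MarkerTable(df, ["age", "fpir"], "outcome")


@pytest.fixture(scope="session")
def planted_marker_cohort():
    """A 600-subject cohort with two planted two-condition rules."""
    specs = tuple(rt.MarkerSpec(f"m{i}") for i in range(8))
    planted = (
        (Rule((Condition("m0", lower=0.5), Condition("m1", upper=0.3))), 2.5),
        (Rule((Condition("m2", upper=-0.4), Condition("m3", lower=-0.2))), 2.5),
    )
    cfg = rt.MarkerGenConfig(
        n_subjects=600,
        marker_specs=specs,
        planted_rules=planted,
        hazard_scale=0.08,
        censor_time=5.0,
        seed=17,
    )
    return rt.sample_marker_cohort(cfg)
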