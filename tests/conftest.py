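import numpy as np
import pytest

from gaitprognosis.cohort import CohortConfig, GaitProfile, simulate_cohort
from gaitprognosis.features import BoutSpec, extract_feature_table


def make_profile(**overrides) -> GaitProfile:
    """A mid-range community-ambulator profile, overridable per test."""
    base = dict(
        gait_speed_adm=0.8,
        gait_speed_dis=1.0,
        cadence=1.6,
        swing_amplitude=160.0,
        pelvis_acc_amplitude=0.25,
        irregularity=0.2,
        asymmetry=0.2,
        fatigue_drift=0.03,
    )
    base.update(overrides)
    return GaitProfile(**base)


@pytest.fixture(scope="session")
def default_cohort():
    """The canonical 33-patient cohort (27 community / 6 household)."""
    return simulate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def fixed_distance_table(default_cohort):
    """Full 71-feature table under the fixed-distance (10 m walk) paradigm."""
    cohort, recordings = default_cohort
    return extract_feature_table(cohort, recordings, BoutSpec("fixed_distance"))


@pytest.fixture(scope="session")
def discharge_labels(default_cohort, fixed_distance_table):
    cohort, _ = default_cohort
    return cohort.loc[fixed_distance_table.index, "label_dis"].to_numpy()


def separator_table(n_per_class: int = 20, n_noise: int = 10, seed: int = 0):
    """A table with one perfectly class-separating feature among pure noise."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    y = np.array(["community"] * n_per_class + ["household"] * n_per_class)
    X = pd.DataFrame(
        rng.normal(size=(2 * n_per_class, n_noise)),
        columns=[f"noise_{i}" for i in range(n_noise)],
    )
    X.insert(0, "separator", np.where(y == "community", 1.0, 0.0) + rng.normal(0, 0.01, 2 * n_per_class))
    return X, y
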