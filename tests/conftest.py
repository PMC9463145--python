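import numpy as np
import pandas as pd
import pytest

import immunotype as it


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced structured cohort shared across tests (same effect structure,
    fewer subjects)."""
    cfg = it.SyntheticConfig(seed=11, n_cases=90, n_controls=100)
    cohort, truth = it.generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def small_processed(small_cohort):
    cohort, truth = small_cohort
    proc = it.run_preprocess(cohort)
    part = cohort.participants.set_index("subject_id")
    case_mask = part.loc[proc.values.index, "group"].eq("case").to_numpy()
    covs = part.loc[proc.values.index, ["female", "bmi"]].reset_index(drop=True)
    return proc, case_mask, covs, truth


@pytest.fixture
def wedge_data():
    """Controls at the origin, cases split between two opposite lobes: the
    canonical geometry the polytope fit must resolve exactly."""
    rng = np.random.default_rng(7)
    controls = rng.normal(0, 0.5, size=(60, 2))
    lobe_a = rng.normal(0, 0.5, size=(25, 2)) + np.array([3.0, 0.0])
    lobe_b = rng.normal(0, 0.5, size=(25, 2)) + np.array([-3.0, 0.0])
    X = np.vstack([controls, lobe_a, lobe_b])
    case_mask = np.array([False] * 60 + [True] * 50)
    lobes = np.array([1] * 25 + [2] * 25)
    return X, case_mask, lobes
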