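import numpy as np
import pandas as pd
import pytest

from immunebalance import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Study-sized synthetic cohort (39 patients / 17 controls, default effects)."""
    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def boosted_cohort():
    """Cohort with effect sizes boosted so group separation is unambiguous."""
    return generate_cohort(SimulationConfig(seed=11).scale_effects(2.5))


@pytest.fixture(scope="session")
def null_cohort_large():
    """n=500/500 cohort with every effect size set to zero."""
    cfg = SimulationConfig(n_patients=500, n_controls=500, effect_sizes={}, seed=5)
    return generate_cohort(cfg)


@pytest.fixture
def three_blob_features():
    """150 samples in three Gaussian blobs separated by ~10 SDs."""
    rng = np.random.default_rng(42)
    centers = np.array([[0.0] * 6, [10.0] * 6, [-10.0] * 6])
    X = np.vstack([rng.normal(c, 1.0, size=(50, 6)) for c in centers])
    labels = np.repeat([0, 1, 2], 50)
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(6)])
    return df, labels
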