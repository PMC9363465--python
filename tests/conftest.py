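import numpy as np
import pandas as pd
import pytest

import ferroscore as fs


@pytest.fixture(scope="session")
def small_cohort():
    """A compact seeded cohort shared by read-only tests."""
    cfg = fs.SimulationConfig(
        seed=42,
        n_samples=80,
        n_features={"mrna": 150, "methylation": 60},
        n_planted_up={"mrna": 5, "methylation": 5},
        n_planted_down={"mrna": 5, "methylation": 5},
    )
    return fs.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    scores = fs.compute_fps(small_cohort.layers["mrna"], small_cohort.signature)
    return fs.dichotomize(scores)


@pytest.fixture()
def toy_matrix():
    rng = np.random.default_rng(7)
    df = pd.DataFrame(
        rng.normal(size=(30, 6)),
        index=[f"g{i}" for i in range(30)],
        columns=[f"s{j}" for j in range(6)],
    )
    return fs.OmicsMatrix(df, "mrna")
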