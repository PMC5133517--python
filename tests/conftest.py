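import numpy as np
import pandas as pd
import pytest

from ibdqt import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_truth():
    """A small but complete synthetic cohort shared across read-only tests."""
    cfg = SimConfig(n_individuals=24, n_markers=200, n_region_variants=60,
                    n_deleterious=10, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_915)


def random_phenotypes(rng, n, n_pcs=3):
    """A random phenotype table with no planted structure."""
    table = pd.DataFrame(
        {
            "id": [f"P{k:03d}" for k in range(n)],
            "dbp": rng.normal(72.0, 9.0, n),
            "treated": rng.random(n) < 0.2,
            "gender": rng.random(n) < 0.5,
            "age": rng.normal(55.0, 15.0, n),
            "smoking": rng.random(n) < 0.25,
        }
    )
    for k in range(n_pcs):
        table[f"pc{k + 1}"] = rng.normal(0.0, 0.05, n)
    return table
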