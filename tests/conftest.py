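import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from agescreen import FeatureMatrix, Phenotype, SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast four-region scenario with planted aging features and TF blocks."""
    return SimulationConfig(
        seed=101,
        n_samples=60,
        n_genes=300,
        n_sites=150,
        fraction_aging=0.15,
        effect_r=0.7,
        n_tfs=2,
        targets_per_tf=25,
    )


@pytest.fixture
def tiny_matrix() -> tuple[FeatureMatrix, Phenotype]:
    """Five samples; one feature equals age, one is its negation, one is a
    hand-crafted partial monotone, one is constant."""
    ages = np.array([31.0, 47.0, 55.0, 62.0, 80.0])
    sids = [f"S{i}" for i in range(5)]
    df = pd.DataFrame(
        {
            "up": ages,
            "down": -ages,
            "mixed": [1.0, 3.0, 2.0, 5.0, 4.0],
            "flat": [2.0] * 5,
        },
        index=sids,
    ).T
    df.columns = sids
    return FeatureMatrix(df), Phenotype(sids, ages)
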