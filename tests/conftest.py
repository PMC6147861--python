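import datetime as dt

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lupine import GenotypeTable, SampleMetadata, SimConfig, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_table() -> GenotypeTable:
    """5 individuals x 3 loci with two missing genotypes (in W3 and W5)."""
    calls = np.array(
        [
            [[100, 102], [140, 140], [90, 92]],
            [[100, 100], [142, 140], [92, 92]],
            [[102, 102], [-1, -1], [90, 90]],
            [[100, 102], [140, 142], [92, 90]],
            [[102, 100], [140, 140], [-1, -1]],
        ]
    )
    return GenotypeTable([f"W{i}" for i in range(1, 6)], ["L1", "L2", "L3"], calls)


@pytest.fixture
def tiny_metadata() -> list[SampleMetadata]:
    return [
        SampleMetadata(f"W{i}", sex="F" if i % 2 else "M", age_class="adult",
                       collection_date=dt.date(2000 + i, 6, 1), x=float(i), y=float(i))
        for i in range(1, 6)
    ]


@pytest.fixture(scope="session")
def wolf_shaped():
    """One paper-shaped synthetic dataset (11 clusters, 207 individuals,
    46 loci, 7 planted dispersers), shared across tests."""
    cfg = SimConfig(seed=17)
    table, metadata, truth = simulate_dataset(cfg)
    return cfg, table, metadata, truth
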