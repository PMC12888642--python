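import numpy as np
import pytest

from fedforest.cohort import (
    GeneratorConfig,
    SiteSpec,
    generate_federated_cohort,
)
from fedforest.local_training import train_local_forest

SMALL_CONFIG = GeneratorConfig(
    specs=(
        SiteSpec("A", 80, 0.30),
        SiteSpec("B", 60, 0.50),
        SiteSpec("C", 50, 0.20),
    ),
    d_binary=6,
    d_continuous=4,
    noise_sd=0.5,
    seed=7,
)


@pytest.fixture(scope="session")
def small_federated():
    """Three tiny synthetic sites sharing one 10-feature schema."""
    return generate_federated_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_models(small_federated):
    """One modest forest per site of the small cohort."""
    return tuple(
        train_local_forest(site, ntree=15, mtry=3, seed=11 + i)
        for i, site in enumerate(small_federated.sites)
    )


@pytest.fixture()
def probe_features(small_federated):
    return small_federated.sites[0].features.iloc[:25]
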