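import numpy as np
import pytest

from terrattrib import (GridSpec, SyntheticTruth, apply_domain_filters,
                        build_feature_table, fit, generate_landscape,
                        split_train)


@pytest.fixture(scope="session")
def bundle64():
    """One 64x64 landscape with half the explainable variance from terrain."""
    truth = SyntheticTruth(seed=7, terrain_share=0.5, interaction_share=0.5,
                           noise_sd=5.0)
    return generate_landscape(GridSpec(64, 64), truth)


@pytest.fixture(scope="session")
def table64(bundle64):
    return apply_domain_filters(build_feature_table(bundle64))


@pytest.fixture(scope="session")
def model64(table64):
    train, _ = split_train(table64, 0.10, seed=7)
    return fit(train, table64.groups, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
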