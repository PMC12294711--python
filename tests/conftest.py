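import warnings

import pytest

from effectorank.synthetic import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic study bundle, shared read-only across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_bundle(SyntheticConfig(rng_seed=0))


@pytest.fixture(scope="session")
def default_partition(default_bundle):
    from effectorank.overlap import intersect_and_partition

    _, partition = intersect_and_partition(
        default_bundle.aging_set, default_bundle.exercise_set
    )
    return partition
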