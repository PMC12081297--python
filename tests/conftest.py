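import pytest

import indeltax as ix
from indeltax import synthdata as sd


@pytest.fixture(scope="session")
def full_scheme():
    return ix.build_full_scheme()


@pytest.fixture(scope="session")
def ind89_scheme():
    return ix.build_ind89_scheme()


@pytest.fixture(scope="session")
def cosmic83_scheme():
    return ix.build_cosmic83_scheme()


@pytest.fixture(scope="session")
def fuzzed_indels():
    """Shared pool of fuzzed normalized InDels over a repeat-rich reference."""
    return sd.random_normalized_indels(20_000, seed=20240)


@pytest.fixture(scope="session")
def planted():
    """Planted events covering every ind89 channel, with truth labels."""
    reqs = sd.default_truth_requests(per_channel=2)
    spec = sd.reference_spec_for(reqs, seed=101)
    reference, features = sd.make_reference(spec)
    variants, truth = sd.plant_indels(reference, features, seed=102)
    return reference, variants, truth
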