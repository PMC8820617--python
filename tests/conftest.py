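import pytest

from cypscreen import FixtureSpec, fixture_records, gen_descriptor_table, gen_ie_profiles


@pytest.fixture(scope="session")
def small_spec():
    """A small separable dataset for fast model tests."""
    return FixtureSpec(
        n_active=100, n_inactive=100, n_informative=5, n_noise=10, effect_size=3.0, seed=11
    )


@pytest.fixture(scope="session")
def small_data(small_spec):
    return gen_descriptor_table(small_spec)


@pytest.fixture(scope="session")
def small_profiles(small_spec, small_data):
    matrix, labels = small_data
    return gen_ie_profiles(matrix.ids, labels, small_spec)


@pytest.fixture(scope="session")
def druglike_records():
    """The embedded fixture molecules that parse and pass the soft filter."""
    return fixture_records(valid_only=True, druglike_only=True)
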