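import pytest

from dqii import default_config, load_reference_table


@pytest.fixture(scope="session")
def food_table():
    return load_reference_table()


@pytest.fixture(scope="session")
def female_config():
    return default_config("female", 35)


@pytest.fixture(scope="session")
def male_config():
    return default_config("male", 35)
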