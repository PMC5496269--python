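import pytest

from saamp import load_kb, load_table
from saamp.predictors import merge_profiles


@pytest.fixture(scope="session")
def kb():
    return load_kb()


@pytest.fixture(scope="session")
def screen_profiles():
    """The 93 variants called damaging by the first four tools."""
    return load_table("damaging_screen").records


@pytest.fixture(scope="session")
def consensus_profiles():
    """The 28 variants further called disease-associated by the last three."""
    return load_table("disease_consensus").records


@pytest.fixture(scope="session")
def merged_profiles(screen_profiles, consensus_profiles):
    return merge_profiles(screen_profiles, consensus_profiles)
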