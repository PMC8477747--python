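import pytest
from hypothesis import settings

from mabscale import builtin_profiles

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def profiles():
    return builtin_profiles()


@pytest.fixture(scope="session")
def animal_profiles(profiles):
    return {k: v for k, v in profiles.items() if k != "human"}
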