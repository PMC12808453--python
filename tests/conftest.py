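import pytest

from hastools.has_typing import build_reference_panels, motif_reference
from hastools.profiles import default_profiles


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def panels(profiles):
    return build_reference_panels(profiles)


@pytest.fixture(scope="session")
def motif_refs(profiles):
    return {t: motif_reference(p) for t, p in profiles.items()}
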