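from pathlib import Path

import pytest

from mopkit import CountryProfile, FixtureSpec, generate_profile, read_profile

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def toy_profile() -> CountryProfile:
    """Hand-built 3-intervention profile (one family-planning row)."""
    return read_profile(DATA_DIR / "toy_profile.json")


@pytest.fixture
def toy_profile_path() -> Path:
    return DATA_DIR / "toy_profile.json"


@pytest.fixture
def synthetic_profile() -> CountryProfile:
    return generate_profile(FixtureSpec(seed=1))
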