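import pytest

import vtescore


@pytest.fixture(scope="session")
def department():
    return vtescore.default_ruleset()


@pytest.fixture(scope="session")
def worked_cases():
    """The 16 bundled postpartum-VTE case profiles with expected scores."""
    return vtescore.load_worked_example_cases()


def make_profile(**overrides):
    """A factor-free term elective cesarean; override fields to add factors."""
    base = dict(
        age=30,
        bmi=22.0,
        weight=56.0,
        parity=1,
        gestational_age_at_delivery=39.0,
        cs_urgency="elective",
        pph_ml=0.0,
    )
    base.update(overrides)
    return base


@pytest.fixture
def profile_factory():
    return make_profile
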