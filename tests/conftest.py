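import pytest

from hemowave import default_tree, fixture_spec, heart_config
from hemowave.pipeline import load_config, run_study


@pytest.fixture(scope="session")
def tree():
    return default_tree()


@pytest.fixture(scope="session")
def baseline_heart():
    return heart_config()


@pytest.fixture(scope="session")
def study_default():
    """Full three-state study on the study-default fixture (expensive)."""
    return run_study()


def _age_config(age):
    cfg = load_config()
    cfg["tree"]["age"] = age
    h = heart_config("baseline", age)
    cfg["heart"].update(Ees=h.Ees, beta=h.beta, Pfill=h.Pfill)
    return cfg


@pytest.fixture(scope="session")
def study_age30():
    return run_study(_age_config("30"))


@pytest.fixture(scope="session")
def study_age70():
    return run_study(_age_config("70"))


@pytest.fixture(scope="session")
def baseline_beat(study_default):
    return study_default.beats["baseline"]
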