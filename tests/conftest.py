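import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    from genoschema import default_registry
    return default_registry()


@pytest.fixture(scope="session")
def schemas(registry):
    return {sid: registry.get(sid) for sid in ("CSHG", "CSCG", "CSG")}


@pytest.fixture(scope="session")
def questions():
    from genoschema.competency import load_questions
    return load_questions()


@pytest.fixture()
def m00021():
    from genoschema.fixtures import cysteine_pathway
    return cysteine_pathway()


@pytest.fixture()
def cftr():
    from genoschema.fixtures import cftr_example
    return cftr_example()
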