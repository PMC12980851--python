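import pytest

from healthkg import DeidConfig, Project
from healthkg.fixtures import (make_patients, make_toy_schema,
                               make_toy_terminology, toy_model,
                               toy_terminology_graph)


@pytest.fixture(scope="session")
def model():
    return toy_model()


@pytest.fixture(scope="session")
def schema_and_oracle():
    return make_toy_schema()


@pytest.fixture(scope="session")
def terminology():
    return toy_terminology_graph()


@pytest.fixture(scope="session")
def clean_bundles(model):
    bundles, ledger = make_patients(model, 30, seed=101)
    assert ledger == []
    return bundles


@pytest.fixture()
def project_factory(tmp_path):
    """Create isolated projects under the test's tmp dir."""

    def factory(project_id="proj", salt="test-salt", deid=True, fmt="trig",
                scramble=(("Subject", "insurance_number"),)):
        schema, _ = make_toy_schema()
        cfg = DeidConfig(scramble_fields=[tuple(s) for s in scramble],
                         project_salt=salt) if deid else None
        return Project.create(tmp_path, project_id, schema, "CHE-123.456.789",
                              serialization_format=fmt, deid_config=cfg,
                              terminology_docs=(make_toy_terminology(),))

    return factory
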