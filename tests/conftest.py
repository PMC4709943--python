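import pytest

from mhcrestrict import classify
from mhcrestrict.fixtures import example_ontology


@pytest.fixture(scope="session")
def ontology():
    return example_ontology()


@pytest.fixture(scope="session")
def hierarchy(ontology):
    return classify(ontology)


@pytest.fixture(scope="session")
def lid(ontology):
    """Resolve a unique label to its term id."""

    def _lid(label):
        return ontology.get_by_label(label).id

    return _lid
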