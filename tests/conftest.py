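import pytest

from semfact import load_dictionary
from semfact.examples import all_examples
from semfact.pipeline import analyze_document


@pytest.fixture(scope="session")
def dictionary():
    return load_dictionary()


@pytest.fixture(scope="session")
def analyses(dictionary):
    """Document id -> (document, pipeline analysis) for every example."""
    out = {}
    for doc in all_examples():
        out[doc.id] = (doc, analyze_document(doc, dictionary=dictionary))
    return out
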