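import pytest

import obai_metrics as om


@pytest.fixture(scope="session")
def backend():
    """One shared rule-backend instance (loads the bundled dictionary once)."""
    return om.get_backend("en")


@pytest.fixture(scope="session")
def easy_words():
    from obai_metrics.io_utils import load_easy_words

    return load_easy_words()


@pytest.fixture(scope="session")
def dictionary():
    from obai_metrics.io_utils import load_dictionary

    return load_dictionary()


@pytest.fixture()
def annotate(backend):
    def _annotate(text: str):
        return om.annotate(text, backend=backend)

    return _annotate


@pytest.fixture(scope="session")
def cat_mat_doc(backend):
    return om.annotate("The cat sat on the mat.", backend=backend)


@pytest.fixture(scope="session")
def possessive_passive_doc(backend):
    """The possessive + passive showcase sentence used across modules."""
    return om.annotate("My friend's house is always decorated beautifully.", backend=backend)
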