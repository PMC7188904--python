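import pytest

from lipidbench.kb import load_knowledge_base


@pytest.fixture(scope="session")
def kb():
    return load_knowledge_base()
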