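import pytest

from pepbloom.mutation import load_blosum62


@pytest.fixture(scope="session")
def blosum62():
    return load_blosum62()
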