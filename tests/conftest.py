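import logging

import pytest

from minichi.synthetic import reference_molecules

logging.getLogger("minichi").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def refs():
    return reference_molecules()
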