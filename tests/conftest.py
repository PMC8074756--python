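import numpy as np
import pytest

from abscopal import synthetic


@pytest.fixture(scope="session")
def axis():
    return synthetic.default_axis()


@pytest.fixture(scope="session")
def library(axis):
    return synthetic.default_reference_library(axis)
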