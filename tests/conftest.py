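import numpy as np
import pytest

from covrf.spatial import build_bank


@pytest.fixture(scope="session")
def default_bank():
    """The full 144-kernel bank (built once per session)."""
    return build_bank()


@pytest.fixture(scope="session")
def small_bank():
    """An 8-kernel bank used by the desk-scale network tests."""
    return build_bank(
        orientations=2, scales=2, skews=1, derivative_set=((1, 0), (0, 1))
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
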