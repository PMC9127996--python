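import pytest

from nitrotherm import default_ground_truth


@pytest.fixture(scope="session")
def gt():
    """Default synthetic ground truth with noise enabled."""
    return default_ground_truth(seed=7)


@pytest.fixture(scope="session")
def gt0():
    """Noise-free variant of the default ground truth."""
    return default_ground_truth(seed=7).noiseless()
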