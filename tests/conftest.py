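import pytest
from hypothesis import settings

from tmfkit import generate_synthetic_foodweb

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def lake_dataset():
    """A typical synthetic lake food web: 12 species, 60 samples,
    true TMF 2.0, residual SD 0.3 log10 units."""
    return generate_synthetic_foodweb(seed=42)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Same design with zero residual noise: the regression is exact."""
    return generate_synthetic_foodweb(resid_sd=0.0, seed=42)
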