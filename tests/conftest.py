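import numpy as np
import pytest

from spinesim import default_model, generate_population


@pytest.fixture(scope="session")
def model():
    """The frozen default synthetic population model."""
    return default_model()


@pytest.fixture(scope="session")
def source(model):
    """A default-model stand-in database (mirrors the 2499-spine reference)."""
    return generate_population(model, 2499, seed=123)


@pytest.fixture(scope="session")
def big_source(model):
    """A larger draw for moment/fraction checks."""
    return generate_population(model, 200_000, seed=321)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


TINY_CSV = """cell_id,spine_id,length_um,head_width_um,neck_width_um,area_um2
c1,s1,1.20,0.45,0.30,0.60
c1,s2,0.80,0.35,0.28,0.40
c2,s3,4.50,0.20,0.15,1.10
"""


@pytest.fixture
def tiny_csv(tmp_path):
    path = tmp_path / "spines.csv"
    path.write_text(TINY_CSV)
    return path
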