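import numpy as np
import pytest

from ocrpipe.intervals import GenomeModel
from ocrpipe.synth import SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def toy_genome() -> GenomeModel:
    return GenomeModel({"chrA": 2_000, "chrB": 3_000})


@pytest.fixture(scope="session")
def bundle():
    """One default synthetic study shared across the suite (seed 1)."""
    return generate_study(SyntheticConfig(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
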