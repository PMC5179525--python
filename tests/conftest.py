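import numpy as np
import pytest

from lrrfam.simulate import FamilySimConfig, simulate_family


@pytest.fixture(scope="session")
def family():
    """Default study-shaped synthetic family (94 genes, 18 subfamilies)."""
    return simulate_family(FamilySimConfig(seed=11))


@pytest.fixture(scope="session")
def family_paraphyletic():
    """Synthetic family with one subfamily's references planted paraphyletic."""
    return simulate_family(FamilySimConfig(seed=12, plant_paraphyly="IX"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
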