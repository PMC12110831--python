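import numpy as np
import pytest

from mitochar import reference
from mitochar.simulate import generate_mitogenome, lactinea_like_spec


@pytest.fixture(scope="session")
def lactinea_annotation():
    """The published gene ledger over a placeholder sequence (geometry only)."""
    return reference.annotation_only_genome()


@pytest.fixture(scope="session")
def synthetic_genome():
    """One study-scale synthetic genome + its manifest (fixed seed)."""
    return generate_mitogenome(lactinea_like_spec(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
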