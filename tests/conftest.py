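import warnings

import numpy as np
import pytest

from egdelim.io_formats import Alignment
from egdelim.subst_models import SubstitutionModel, get_preset
from egdelim.synthetic_data import generate_fixture

# simulators emit benign saturation/ambiguity warnings on extreme draws
warnings.filterwarnings("ignore", message=".*saturated.*")


@pytest.fixture(scope="session")
def jc_model() -> SubstitutionModel:
    """Jukes-Cantor: equal frequencies, equal exchangeabilities, no +I/+G."""
    return SubstitutionModel([0.25] * 4, [1.0] * 6)


@pytest.fixture(scope="session")
def coi_model() -> SubstitutionModel:
    return get_preset("coi_paper")


@pytest.fixture(scope="session")
def its2_model() -> SubstitutionModel:
    return get_preset("its2_paper")


@pytest.fixture(scope="session")
def coi_fixture():
    """58-specimen, 29-haplotype COI-like dataset (seed 1)."""
    return generate_fixture("coi_like", seed=1)


@pytest.fixture(scope="session")
def its2_fixture():
    """22-specimen, 14-haplotype ITS2-like dataset (seed 1)."""
    return generate_fixture("its2_like", seed=1)


def make_pair(p: float, L: int = 1200) -> Alignment:
    """Two sequences differing at an exact fraction p of sites."""
    k = round(p * L)
    assert abs(k / L - p) < 1e-12, "p*L must be integral"
    a = "A" * L
    b = "C" * k + "A" * (L - k)
    return Alignment.from_records([("a", a), ("b", b)])


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20120703)
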