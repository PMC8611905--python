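import numpy as np
import pytest

from survclustae import OmicsMatrix, OmicsType, SurvivalTable
from survclustae.synthetic import easy_fixture


@pytest.fixture(scope="session")
def easy():
    """Canonical planted-subgroup cohort (120 x 630, k=2, effect 3, HRs 1/5)."""
    return easy_fixture()


@pytest.fixture()
def small_omics():
    rng = np.random.default_rng(42)
    values = rng.normal(5.0, 1.0, size=(10, 6))
    return OmicsMatrix(values, [f"S{i}" for i in range(10)],
                       [f"g{j}" for j in range(6)], OmicsType.MRNA)


@pytest.fixture()
def small_survival():
    rng = np.random.default_rng(1)
    return SurvivalTable([f"S{i}" for i in range(10)],
                         rng.exponential(500.0, 10).round(1),
                         np.array([1, 0, 1, 1, 0, 1, 1, 1, 0, 1]))
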