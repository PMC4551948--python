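import numpy as np
import pytest

from anisokin import OpticalParams, Protocol, RateSet
from anisokin import reference as ref


@pytest.fixture(scope="session")
def wt_rates() -> RateSet:
    """Full-RNP 22 degC parameter set."""
    return ref.WT_22C


@pytest.fixture(scope="session")
def dgar1_rates() -> RateSet:
    """Gar1-free 22 degC parameter set (slow catalysis)."""
    return ref.DGAR1_22C


@pytest.fixture(scope="session")
def optics() -> OpticalParams:
    return OpticalParams()


@pytest.fixture(scope="session")
def noiseless_optics() -> OpticalParams:
    return OpticalParams(shot_noise=False)


def random_rate_sets(n: int, seed: int = 0) -> list[RateSet]:
    """n random admissible rate sets with well-spread magnitudes."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(
            RateSet(
                k_on_S=10 ** rng.uniform(2, 5),
                k_off_S=10 ** rng.uniform(-4, -2),
                k_cat=10 ** rng.uniform(-4, -2),
                k_off_P=10 ** rng.uniform(-4, -1.5),
                k_on_P=10 ** rng.uniform(2, 5),
            )
        )
    return out
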