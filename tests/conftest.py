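import numpy as np
import pytest

import ecospheroid as es
from ecospheroid import presets


@pytest.fixture(scope="session")
def pc3_parental():
    return presets.PC3_PARENTAL


@pytest.fixture(scope="session")
def pc3_rr():
    return presets.PC3_RADIORESISTANT


@pytest.fixture(scope="session")
def du145_parental():
    return presets.DU145_PARENTAL


@pytest.fixture(scope="session")
def du145_rr():
    return presets.DU145_RADIORESISTANT


@pytest.fixture(scope="session")
def lq_pair():
    return presets.LQ_PC3_PARENTAL, presets.LQ_PC3_RADIORESISTANT


@pytest.fixture(scope="session")
def protocol():
    return presets.DEFAULT_PROTOCOL


@pytest.fixture
def small_ca_params():
    """Fast CA configuration for unit tests (coarse grid)."""
    return es.CAParams(grid_size=60, seed=11)


def random_lv_params(rng: np.random.Generator,
                     lam_lo: float = -0.5, lam_hi: float = 0.9) -> es.LVParams:
    """Random but well-posed LV parameter draw for property tests."""
    return es.LVParams(
        r_P=rng.uniform(0.1, 0.5), r_RR=rng.uniform(0.1, 0.5),
        K_P=rng.uniform(0.5, 1.5), K_RR=rng.uniform(1.0, 3.0),
        lambda_P=rng.uniform(lam_lo, lam_hi),
        lambda_RR=rng.uniform(lam_lo, lam_hi),
        V_P0=rng.uniform(0.02, 0.08), V_RR0=rng.uniform(0.02, 0.08),
    )
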