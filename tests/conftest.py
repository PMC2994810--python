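import numpy as np
import pytest

from eggdosage.pools import ACTB, FETAL, MATERNAL, MoleculePool, VAPA_APCDD1, ZFY


@pytest.fixture
def mixed_pool() -> MoleculePool:
    """Small pool with methylated fetal marker, unmethylated background, ZFY."""
    pool = MoleculePool()
    pool.add(VAPA_APCDD1, FETAL, (True,) * 5, 12)
    pool.add(VAPA_APCDD1, FETAL, (True, True, True, True, False), 3)
    pool.add(VAPA_APCDD1, MATERNAL, (False,) * 5, 500)
    pool.add(ZFY, FETAL, (), 20)
    pool.add(ACTB, FETAL, (False,) * 4, 30)
    pool.add(ACTB, MATERNAL, (False,) * 4, 400)
    return pool


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
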