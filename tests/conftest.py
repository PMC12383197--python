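import numpy as np
import pytest

from mbgp.presets import get_preset
from mbgp.scenarios import qc_replicate, simulate_replicate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def micro_replicate():
    """One fully simulated and QC'd micro-scale replicate, shared by tests."""
    rep = simulate_replicate(get_preset("micro"), 7)
    return qc_replicate(rep)


def random_pedigree(rng, n, founder_fraction=0.3):
    """Random valid pedigree (parents precede offspring) with some inbreeding."""
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    n_founders = max(2, int(founder_fraction * n))
    for i in range(n_founders, n):
        sire[i] = rng.integers(0, i)
        dam[i] = rng.integers(0, i)
    return sire, dam
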