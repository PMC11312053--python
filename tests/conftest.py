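import numpy as np
import pytest
from hypothesis import settings

from pubag.augment import PUPools
from pubag.chem_io import CompoundRecord
from pubag.featurize import FingerprintConfig, FingerprintKind, FingerprintMatrix

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def bioactivity_records():
    return [
        CompoundRecord("mol1", "CCO", 7.8),
        CompoundRecord("mol2", "c1ccccc1", 7.0),
        CompoundRecord("mol3", "CC(=O)O", 6.0),
        CompoundRecord("mol4", "CCN", 8.2),
        CompoundRecord("mol5", "CCCC", 5.1),
    ]


def random_fp_matrix(n, n_bits=32, seed=0, prefix="c"):
    rng = np.random.default_rng(seed)
    bits = (rng.random((n, n_bits)) < 0.2).astype(np.uint8)
    ids = [f"{prefix}{i}" for i in range(n)]
    cfg = FingerprintConfig(kind=FingerprintKind.OTHER, n_bits=n_bits)
    return FingerprintMatrix(ids, bits, cfg)


def toy_pools(n_pos=20, n_neg=10, n_put=15, n_unl=60, n_bits=32, seed=0):
    """Small, linearly structured pools: positives carry a dense bit block
    that non-positives lack."""
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg + n_put + n_unl
    bits = (rng.random((n, n_bits)) < 0.15).astype(np.uint8)
    bits[:n_pos, : n_bits // 4] = 1  # positive signature block
    ids = [f"t{i}" for i in range(n)]
    cfg = FingerprintConfig(kind=FingerprintKind.OTHER, n_bits=n_bits)
    fps = FingerprintMatrix(ids, bits, cfg)
    pos = ids[:n_pos]
    neg = ids[n_pos:n_pos + n_neg]
    put = ids[n_pos + n_neg:n_pos + n_neg + n_put]
    unl = ids[n_pos + n_neg + n_put:]
    return fps, PUPools(frozenset(pos), frozenset(neg), frozenset(put),
                        frozenset(unl))


@pytest.fixture
def toy():
    return toy_pools()
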