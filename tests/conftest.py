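import numpy as np
import pytest

from epimux import EpitopeMaskSet, EPITOPES


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_maskset(n, p, c, tissue=None):
    """Build an EpitopeMaskSet from three boolean arrays."""
    n = np.asarray(n, bool)
    if tissue is None:
        tissue = np.ones_like(n)
    return EpitopeMaskSet(
        masks={"Nterm": n, "pS129": np.asarray(p, bool),
               "Cterm": np.asarray(c, bool)},
        tissue_mask=np.asarray(tissue, bool),
    )


def random_maskset(rng, shape=(32, 32), density=0.3):
    masks = [rng.random(shape) < density for _ in range(3)]
    return make_maskset(*masks)


@pytest.fixture
def maskset_factory():
    return make_maskset
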