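import numpy as np
import pytest

from lease_nas import nn
from lease_nas.explanations import LabeledBatch
from lease_nas.search_space import OperationVocabulary, build_supernet


@pytest.fixture
def rng():
    return np.random.default_rng(0)


TINY_VOCAB = OperationVocabulary(("zero", "avg_pool_3x3", "dil_conv_3x3"))


def make_tiny_supernet(seed=0, dtype=np.float64):
    """A deliberately small supernet (<200 parameters, 4x4 inputs) so that
    full coordinate-wise numerical differentiation stays cheap."""
    return build_supernet(
        cells=2, num_nodes=1, init_channels=1, num_classes=4, in_channels=1,
        vocab=TINY_VOCAB, stem_multiplier=1, seed=seed, dtype=dtype,
    )


def make_batch(rng, n=3, size=4, num_classes=4, dtype=np.float64):
    return LabeledBatch(
        rng.uniform(0.0, 1.0, size=(n, 1, size, size)).astype(dtype),
        rng.integers(0, num_classes, size=n),
    )


def numeric_grad(f, arr, indices=None, h=1e-5):
    """Central finite differences of scalar f() w.r.t. entries of arr."""
    flat = arr.ravel()
    idx = range(flat.size) if indices is None else indices
    out = {}
    for i in idx:
        orig = flat[i]
        flat[i] = orig + h
        fp = f()
        flat[i] = orig - h
        fm = f()
        flat[i] = orig
        out[i] = (fp - fm) / (2 * h)
    return out
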