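import numpy as np
import pytest

from xintnmf.data_model import MultiOmicsDataset, OmicsLayer


def make_layer(layer_id, m, n, rng, prefix=None):
    prefix = prefix or layer_id
    values = rng.random((m, n)) + 0.01
    return OmicsLayer(
        layer_id,
        [f"{prefix}_f{i}" for i in range(m)],
        [f"S{j}" for j in range(n)],
        values,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """Two layers (8 and 5 features) over 6 shared samples."""
    return MultiOmicsDataset([make_layer("mRNA", 8, 6, rng), make_layer("miRNA", 5, 6, rng)])
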