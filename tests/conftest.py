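import numpy as np
import pytest

import fedlatent as fl


@pytest.fixture
def tiny_dnn_spec():
    return fl.ModelSpec(kind="dnn", input_shape=(5,), num_classes=3, hidden_width=7)


@pytest.fixture
def tiny_cnn_spec():
    return fl.ModelSpec(kind="cnn", input_shape=(10, 10), num_classes=3,
                        hidden_width=8, conv_filters=4)


@pytest.fixture
def small_dataset():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((40, 5))
    y = rng.integers(0, 3, 40)
    return fl.ClientDataset(x, y, client_id=0)


def make_signature(client_id, n=100, l=2, variance=1.0, histogram=None, bins=4):
    if histogram is None:
        histogram = np.full(bins, 1.0 / bins)
    return fl.LatentSignature(histogram=np.asarray(histogram), variance=variance,
                              sample_count=n, label_class_count=l,
                              client_id=client_id)


@pytest.fixture
def signature_factory():
    return make_signature
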