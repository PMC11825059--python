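import numpy as np
import pytest

from supcon_tsc import EncoderConfig, build_network


@pytest.fixture
def tiny_cfg():
    """A small architecture that keeps unit tests fast."""
    return EncoderConfig(in_channels=2, n_classes=3, block_filters=(4, 6, 6),
                         kernel_sizes=(8, 5, 3), proj_dim=5, proj_hidden=8,
                         clf_hidden=8)


@pytest.fixture
def tiny_net(tiny_cfg):
    return build_network(tiny_cfg, seed=1)


@pytest.fixture
def ts_file(tmp_path):
    """2-case, 2-channel, length-4 .ts fixture with labels {a, b}."""
    p = tmp_path / "toy.ts"
    p.write_text(
        "@problemName toy\n"
        "@timeStamps false\n"
        "@univariate false\n"
        "@classLabel true a b\n"
        "@data\n"
        "1,2,3,4:5,6,7,8:a\n"
        "9,8,7,6:5,4,3,2:b\n"
    )
    return p


@pytest.fixture
def ragged_ts_file(tmp_path):
    """One case of length 3, one of length 5."""
    p = tmp_path / "ragged.ts"
    p.write_text(
        "@problemName ragged\n"
        "@classLabel true a b\n"
        "@data\n"
        "1,2,3:10,20,30:a\n"
        "4,5,6,7,8:40,50,60,70,80:b\n"
    )
    return p


def rng(seed=0):
    return np.random.default_rng(seed)
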