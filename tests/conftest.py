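import numpy as np
import pytest

import cspanet as cn


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_dataset(tmp_path_factory):
    """The default synthetic study: 100 patients/class, 1 ECG each, seed 7.

    Generated once per session; returns (manifest, root, preloaded arrays
    at the desk input size).
    """
    root = tmp_path_factory.mktemp("desk_ds")
    cfg = cn.SynthConfig()
    manifest = cn.generate_dataset(cfg, root)
    data = cn.load_dataset_arrays(manifest, root, (256, 128))
    return manifest, root, data


def tiny_network_config(attention="cspa", stem_enabled=True, seed=0,
                        input_size=(64, 32)):
    """A micro backbone for fast structural/training tests."""
    stem = cn.StemConfig(channel_widths=(4, 6, 8), strides=(2, 2, 1),
                         enabled=stem_enabled)
    widths = (8, 8, 16, 16, 32, 32)
    blocks, in_ch = [], stem.out_channels
    for i, out in enumerate(widths):
        blocks.append(cn.BottleneckConfig(
            in_channels=in_ch, mid_channels=max(out // 4, 2), out_channels=out,
            stride=2 if i % 2 == 0 else 1, attention_name=attention))
        in_ch = out
    return cn.NetworkConfig(stem=stem, blocks=tuple(blocks),
                            input_size=input_size, seed=seed)
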