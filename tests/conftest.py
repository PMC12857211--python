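import numpy as np
import pandas as pd
import pytest

from wallpore.volume_io import LabeledVolume


def make_volume(labels, spacing=(1.0, 1.0, 1.0), channel="cell"):
    return LabeledVolume(
        labels=np.asarray(labels, dtype=np.int32), spacing=spacing, channel=channel
    )


def type_table(mapping):
    return pd.DataFrame(
        {"cell_label": list(mapping), "cell_type": list(mapping.values())}
    )


@pytest.fixture
def two_cell_volume():
    """Two 1-voxel cells side by side along x: one TP interface of one face."""
    labels = np.zeros((1, 1, 2), dtype=np.int32)
    labels[0, 0, 0] = 1
    labels[0, 0, 1] = 2
    vol = make_volume(labels)
    types = type_table({1: "TC", 2: "PC"})
    return vol, types


@pytest.fixture
def flat_wall_volume():
    """Two-slab volume: a single flat z-normal wall spanning y-x."""

    def build(ny, nx, spacing=(1.0, 1.0, 1.0), types=("TC", "TC")):
        labels = np.ones((4, ny, nx), dtype=np.int32)
        labels[2:] = 2
        vol = make_volume(labels, spacing=spacing)
        return vol, type_table({1: types[0], 2: types[1]})

    return build
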