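import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from nichemech import synth  # noqa: E402


@pytest.fixture(scope="session")
def uniform_scene():
    """Three isolated cells with spatially uniform antigen."""
    spec = synth.SceneSpec(n_cells=3, seed=1)
    return synth.gen_cell_scene(spec)


@pytest.fixture(scope="session")
def edge_scene():
    """Cells with a 2x peripheral (cortical) enrichment band."""
    spec = synth.SceneSpec(
        n_cells=3, seed=2,
        channels={"pmlc": synth.ChannelModel(edge_multiplier=2.0)})
    return synth.gen_cell_scene(spec)


@pytest.fixture(scope="session")
def nuclear_scene():
    """Cells with 3x nuclear-enriched antigen."""
    spec = synth.SceneSpec(
        n_cells=3, seed=3,
        channels={"notch": synth.ChannelModel(nucleus_multiplier=3.0)})
    return synth.gen_cell_scene(spec)


def mask_iou(a, b):
    return (a & b).sum() / (a | b).sum()


def match_truth(record, truth):
    """Ground-truth mask best overlapping a segmented record."""
    best = max(range(1, truth.labels.max() + 1),
               key=lambda l: (record.cell_mask & (truth.labels == l)).sum())
    return truth.labels == best, best


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
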