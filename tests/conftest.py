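import numpy as np
import pytest

from statedyn.design import build_block_design
from statedyn.io import RoiTimeSeries
from statedyn.simulate import SyntheticConfig


@pytest.fixture(scope="session")
def study_design():
    """The study's stimulation timeline: 360 s rest + 8 x (20 s ON / 80 s OFF)."""
    return build_block_design(360, 8, 20, 80, 1)


@pytest.fixture()
def tiny_design():
    return build_block_design(10, 2, 5, 5, 1)


def reduced_config(**overrides):
    """Small synthetic-study configuration for fast fitting tests.

    Fewer ROIs keep the per-state parameter cost low enough that a short
    run still supports distinct ON/OFF states.
    """
    base = dict(n_experimental=4, n_control=3, n_rois=5, rest_duration=60,
                n_epochs=4, on_duration=20, off_duration=40, seed=0)
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_ts(data, labels=None, subject_id="s1", group="experimental", tr=1.0):
    data = np.asarray(data, float)
    if labels is None:
        labels = tuple(f"r{i}" for i in range(data.shape[1]))
    return RoiTimeSeries(subject_id=subject_id, group=group, data=data,
                         roi_labels=tuple(labels), tr=tr)
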