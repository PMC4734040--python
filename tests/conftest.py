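import numpy as np
import pytest

from plsmix.dataset import TimeSeriesDataset
from plsmix.inference import IMPLSHyperParams
from plsmix.segmentation import Segmentation, build_design_matrix


@pytest.fixture
def tiny_dataset() -> TimeSeriesDataset:
    return TimeSeriesDataset(
        ["g1", "g2"],
        np.array([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]]),
        np.array([0.0, 10.0, 20.0]),
    )


@pytest.fixture
def two_segment_model():
    seg = Segmentation(((0, 2), (2, 4)))
    return build_design_matrix(seg, np.array([0.0, 1.0, 2.0, 3.0]))


@pytest.fixture
def small_hypers() -> IMPLSHyperParams:
    return IMPLSHyperParams(
        alpha=1.0, d=0.1, a=2.0, b=1.0, v_init=4.0, v_jump=3.0, v_slope=2.0
    )


def enumerate_partitions(items: list):
    """All set partitions of a list (restricted-growth enumeration)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for partition in enumerate_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1:]
        yield [[first]] + partition
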