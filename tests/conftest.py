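import numpy as np
import pytest

from chronocal import Calibration, parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_tip_tree():
    return parse_newick("(A:200,B:200)R;")


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:5,B:5)I:5,C:10)R;")


@pytest.fixture
def testudines_root_cal():
    """Crown-turtle root window: 155.6--251.4 Ma, 2.5% soft upper tail."""
    return Calibration("R", "uniform", 155.6, 251.4)


@pytest.fixture
def nested_cals():
    """Root and inner windows that overlap, forcing visible truncation."""
    return [
        Calibration("R", "uniform", 10, 20),
        Calibration("I", "uniform", 5, 15),
    ]
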