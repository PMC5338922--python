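import numpy as np
import pytest

from irsretina import analysis, circuit
from irsretina.stimulus import GratingSpec


@pytest.fixture(scope="session")
def spec():
    return GratingSpec()


@pytest.fixture(scope="session")
def params():
    return circuit.CircuitParams()


@pytest.fixture(scope="session")
def std_traces(spec, params):
    """Model rate traces for the 16 standard saccadic transitions."""
    return circuit.transition_traces(spec, params)


@pytest.fixture(scope="session")
def gray_traces(spec, params):
    return circuit.transition_traces(spec, params, kind="gray_mask")


@pytest.fixture(scope="session")
def std_matrix(std_traces):
    return analysis.matrix_from_traces(std_traces)


def post_fixation_peak(trace, lo=50.0, hi=200.0, fixation_onset=100.0):
    """Max model rate in the detection window after fixation onset."""
    return float(trace.window(fixation_onset + lo, fixation_onset + hi).max())


def change_keys(n=4):
    return [(s, t) for s in range(1, n + 1) for t in range(1, n + 1) if s != t]
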