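import numpy as np
import pytest

from chronowave import ChirpSpec, MorletParams, TimeSeries, make_signal_a, morlet_cwt


@pytest.fixture(scope="session")
def signal_a():
    """Noise-free default chirp (period 24 -> 18 h over 10 days, hourly)."""
    return make_signal_a(ChirpSpec())


@pytest.fixture(scope="session")
def signal_a_cwt(signal_a):
    return morlet_cwt(signal_a, MorletParams(edge_mode="truncate"))


@pytest.fixture()
def cosine24():
    """Unit cosine, period 24 h, 480 hourly samples."""
    t = np.arange(480.0)
    return TimeSeries(np.cos(2 * np.pi * t / 24.0), dt=1.0, label="cos24")


def cell_valid_columns(result, ridge):
    """Columns where the ridge estimate is reportable under truncation."""
    cols = np.arange(result.n)
    valid = ridge.valid.copy()
    if result.params.edge_mode == "truncate":
        valid &= result.edge_valid[ridge.row_index, cols]
    return np.flatnonzero(valid)
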