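import numpy as np
import pytest

from mibci.montage import standard_layout, small_montage
from mibci.synthgen import SynthConfig, generate_session


@pytest.fixture(scope="session")
def layout():
    return standard_layout(64)


@pytest.fixture(scope="session")
def small_layout(layout):
    return layout.subset(small_montage(layout))


@pytest.fixture(scope="session")
def short_session(small_layout):
    """Two runs, 9 channels, moderate ERD — a cheap shared recording."""
    cfg = SynthConfig(n_runs=2, trials_per_run=25, erd_depth=0.8, snr=5.0, seed=42)
    rec, sch = generate_session(cfg, small_layout)
    return cfg, rec, sch


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
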