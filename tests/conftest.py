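import numpy as np
import pytest

from fecgdenoise.simulator import SimulationCase, simulate_case


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_record():
    """A 60 s case0 record at -6 dB, shared across tests."""
    case = SimulationCase(case_id="case0", snr_db=-6.0, duration_s=60.0,
                          fs=250.0, seed=7)
    return simulate_case(case)


@pytest.fixture(scope="session")
def clean_fetal_channel():
    """A clean single-channel fetal trace with known beat locations."""
    case = SimulationCase(case_id="baseline", snr_db=0.0, duration_s=60.0,
                          fs=250.0, seed=11)
    rec = simulate_case(case)
    return rec.clean[0], rec.fetal_peaks, rec.fs
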