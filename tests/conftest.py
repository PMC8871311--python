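import logging

import numpy as np
import pytest

from eegfusion import EEGRecord, SynthConfig, generate_record
from eegfusion._edf import write_edf

# padding warnings are expected on degenerate synthetic segments
logging.getLogger("eegfusion.features").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def edf_fixture(tmp_path):
    """A 60 s, 4-channel, 256 Hz synthetic EDF file plus the record it encodes."""
    cfg = SynthConfig(fs=256.0, n_channels=4, duration_s=60.0, seed=11,
                      ictal_intervals=())
    rec = generate_record(cfg)
    path = tmp_path / "fixture.edf"
    write_edf(rec, path)
    return path, rec


@pytest.fixture
def single_channel_record(rng):
    """A 1-channel 4096-sample record (canonical ASCII-dialect length)."""
    return EEGRecord(rng.standard_normal(4096) * 40.0, fs=173.6)
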