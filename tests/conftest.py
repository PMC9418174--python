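import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from mrimon.series import DECAY, IR
from mrimon.synth import SignalGenConfig, generate_decay_series, generate_ir_series
from mrimon.synth.signals import DEFAULT_ECHO_SCHEDULE, DEFAULT_IR_SCHEDULE


@pytest.fixture
def ir_noiseless():
    """Signed noiseless IR series from a=1000, b=1800, T1*=600 (T1=480)."""
    cfg = SignalGenConfig(
        IR, {"a": 1000.0, "b": 1800.0, "t1_star": 600.0},
        schedule=DEFAULT_IR_SCHEDULE, noise_sigma=0.0, magnitude_mode=False,
    )
    return generate_ir_series(cfg)


@pytest.fixture
def decay_noiseless():
    """Noiseless echo decay from M0=1000, T2=14 ms, c=50 on the 14-echo train."""
    cfg = SignalGenConfig(
        DECAY, {"m0": 1000.0, "t2": 14.0, "c": 50.0},
        schedule=DEFAULT_ECHO_SCHEDULE, noise_sigma=0.0, magnitude_mode=False,
    )
    return generate_decay_series(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
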