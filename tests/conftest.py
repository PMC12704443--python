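import numpy as np
import pytest

from mwbody import synth


@pytest.fixture(scope="session")
def bf_recording() -> synth.SimRecording:
    """One moderate-noise breathing-focused session with ground truth."""
    cfg = synth.SimConfig(duration=300.0, n_mw_reports=6, seed=5, condition="BF")
    return synth.simulate_recording(cfg)


@pytest.fixture(scope="session")
def sf_recording() -> synth.SimRecording:
    cfg = synth.SimConfig(duration=300.0, n_mw_reports=6, seed=11, condition="SF")
    return synth.simulate_recording(cfg)


@pytest.fixture(scope="session")
def small_study():
    """Three participants x two conditions, short sessions."""
    return synth.simulate_study(3, seed=21, duration=240.0, n_mw_reports=6)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
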