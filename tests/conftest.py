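import numpy as np
import pytest

from vnspupil import AnalysisConfig
from vnspupil import synth
from vnspupil.session import SessionMeta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def config():
    cfg = AnalysisConfig()
    cfg.n_bootstrap = 200  # keep unit-level bootstraps light
    return cfg


@pytest.fixture(scope="session")
def full_protocol():
    """One repetition of the 5x4x3 exploration grid (60 trains)."""
    return synth.generate_protocol(synth.FULL_GRID, repetitions=1, seed=11)


@pytest.fixture(scope="session")
def small_session():
    """A short standard-luminance session: 12 trains, compressed intervals.

    Compressed intertrain intervals keep the simulated recording small; the
    evoked/baseline statistics per trial are unaffected because successive
    windows do not overlap.
    """
    protocol = synth.generate_protocol(
        ((0.1, 0.5, 0.9), (0.2, 0.8), (10.0, 20.0)),
        repetitions=1, seed=3, intertrain=(40.0, 50.0), t_start=40.0)
    truth = synth.GroundTruthParams(blink_rate_per_min=1.0)
    record, notes = synth.generate_session(protocol, truth, seed=4,
                                           pupil_rate=50.0)
    return record, notes, truth


@pytest.fixture(scope="session")
def imaging_session():
    """A compact axon-imaging session with a fluorescence channel."""
    protocol = synth.generate_protocol(
        synth.IMAGING_GRID, repetitions=1, seed=5,
        intertrain=(60.0, 70.0), t_start=60.0)
    meta = SessionMeta(experiment_kind="axon_imaging", luminance_class="imaging",
                      session_id="imaging_test")
    truth = synth.GroundTruthParams(blink_rate_per_min=0.5)
    record, notes = synth.generate_session(protocol, truth, seed=6, meta=meta)
    return record, notes, truth
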