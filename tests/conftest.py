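import numpy as np
import pytest

import pupilbci as pb


@pytest.fixture(scope="session")
def default_session():
    """One default synthetic block (25 trials, 5 min), generated once."""
    return pb.generate_session(pb.SynthConfig(), seed=7)


@pytest.fixture(scope="session")
def preprocessed_trials(default_session):
    """Preprocessed, epoched trials from the default block."""
    processed = pb.preprocess_session(default_session)
    trials, dropped = pb.epoch_session(processed)
    assert dropped == 0
    return trials


@pytest.fixture(scope="session")
def strong_erd_trials():
    """A 60-trial block with deep planted ERD: near-separable EEG classes."""
    cfg = pb.SynthConfig(erd_depth=0.85, sensor_noise_sd=2.0,
                         n_trials_per_block=60, block_seconds=60 * 12 + 6)
    session = pb.generate_session(cfg, seed=11)
    trials, _ = pb.epoch_session(pb.preprocess_session(session))
    return trials


def random_spd(rng, n):
    """Random symmetric positive-definite matrix."""
    a = rng.standard_normal((n, n))
    return a @ a.T + n * np.eye(n) * 0.1
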