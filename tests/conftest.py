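import numpy as np
import pytest

from psgpipe import CohortDesign, sample_hypnogram, synthesize_signals


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_recording():
    """One 1-h tail-handled recording with its ground truth (session-cached)."""
    design = CohortDesign(
        n_per_group=1, cells=(("TH", "Veh"),), duration_hours=1.0, seed=42
    )
    truth = sample_hypnogram(design, ("TH", "Veh"), 0)
    rec = synthesize_signals(truth, design.state_params, rng_seed=99)
    return rec, truth
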