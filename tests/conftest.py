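import numpy as np
import pytest

import amsanet as a


@pytest.fixture(scope="session")
def vf_segment():
    """One default synthetic VF segment (4 s, 250 Hz)."""
    return a.generate_vf(rng_seed=11)


@pytest.fixture(scope="session")
def cc_artifact():
    """One default synthetic compression artifact with its cycle onsets."""
    return a.generate_cc_artifact(rng_seed=12)


@pytest.fixture(scope="session")
def stationary_cc_params():
    """Perfectly periodic artifact: no cycle jitter, no magnitude modulation."""
    return a.CcGenParams(cycle_jitter_cv=0.0, magnitude_mod_sigma=0.0)


@pytest.fixture
def sinusoid_segment():
    def make(freq_hz=5.0, amp_mv=1.0, duration=4.0, fs=250.0):
        t = np.arange(int(duration * fs)) / fs
        return a.EcgSegment(samples=amp_mv * np.sin(2 * np.pi * freq_hz * t), fs=fs)

    return make


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small subject-tagged dataset for model plumbing tests."""
    cfg = a.DatasetConfig(seed=5, n_subjects=10, pairs_per_subject=2)
    return a.build_dataset(cfg)
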