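"""Shared fixtures: small simulated sessions reused across test modules."""

import numpy as np
import pytest

from dialogtrf.segmentation import detect_ipus, extract_training_samples, label_conditions
from dialogtrf.simulate import DialogueSpec, GroundTruth, default_kernel_bank, simulate_session


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def make_session(duration_s=120.0, n_channels=4, n_features=16, seed=11, snr=10.0,
                 gain_self=0.0, gain_other=1.0, crosstalk=0.0):
    spec = DialogueSpec(
        duration_s=duration_s, n_channels=n_channels, n_features=n_features, seed=seed
    )
    kernels = default_kernel_bank(
        n_channels, n_features, rng=np.random.default_rng(seed + 1)
    )
    gt = GroundTruth(
        kernels=kernels, gain_other=gain_other, gain_self=gain_self,
        crosstalk=crosstalk, seed=seed + 2,
    )
    return simulate_session(spec, gt, snr=snr)


def condition_mask(session):
    return label_conditions(
        detect_ipus(session.track_self.activity, speaker="self"),
        detect_ipus(session.track_other.activity, speaker="other"),
        session.spec.n_frames,
        session.spec.fs_feature,
    )


@pytest.fixture(scope="session")
def small_session():
    """120 s suppressed-self session, 4 channels, SNR 10."""
    return make_session()


@pytest.fixture(scope="session")
def small_mask(small_session):
    return condition_mask(small_session)


@pytest.fixture(scope="session")
def e_samples(small_mask):
    return extract_training_samples(small_mask, "E")
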