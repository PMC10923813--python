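"""Synthetic dialog generator: turn-taking, kernels, EEG synthesis."""

import numpy as np
import pytest

from dialogtrf.simulate import (
    _MIN_TURN_S,
    DialogueSpec,
    GroundTruth,
    InvalidSpecError,
    make_kernel,
    pink_noise,
    rasterize_intervals,
    sample_dialogue,
    synthesize_eeg,
)

from conftest import condition_mask, make_session


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(duration_s=0.0),
        dict(duration_s=-5.0),
        dict(overlap_prob=1.5),
        dict(overlap_prob=-0.1),
        dict(fs_audio=16001),
        dict(turn_mean_s=0.0),
    ],
)
def test_invalid_spec_rejected(kwargs):
    with pytest.raises(InvalidSpecError):
        DialogueSpec(**kwargs)


def test_no_overlap_when_probability_zero():
    spec = DialogueSpec(duration_s=200.0, overlap_prob=0.0, seed=5)
    a, b = sample_dialogue(spec)
    both = a.activity_mask() & b.activity_mask()
    assert not both.any()


def test_seeded_determinism():
    spec = DialogueSpec(duration_s=60.0, seed=42)
    a1, b1 = sample_dialogue(spec)
    a2, b2 = sample_dialogue(spec)
    assert a1.activity == a2.activity and b1.activity == b2.activity
    np.testing.assert_array_equal(a1.features, a2.features)
    np.testing.assert_array_equal(b1.features, b2.features)


def test_features_zero_outside_activity():
    spec = DialogueSpec(duration_s=90.0, seed=3)
    a, _ = sample_dialogue(spec)
    silent = ~a.activity_mask()
    assert np.all(a.features[:, silent] == 0)
    assert np.any(a.features[:, ~silent] > 0)


def test_condition_durations_partition_session():
    session = make_session(duration_s=90.0, seed=17)
    counts = condition_mask(session).counts()
    assert sum(counts.values()) == session.spec.n_frames
    assert counts["B"] > 0  # overlap occurs with default overlap_prob


def _overlap_fraction(track_a, track_b, spec):
    both = track_a.activity_mask() & track_b.activity_mask()
    return both.mean()


def _oracle_turn_taking(spec, rng):
    """Independent reimplementation of the generative turn-taking rules."""
    intervals = ([], [])
    speaker = int(rng.integers(2))
    t = rng.exponential(spec.pause_mean_s)
    while t < spec.duration_s:
        length = _MIN_TURN_S + rng.exponential(spec.turn_mean_s)
        end = min(t + length, spec.duration_s)
        if end - t >= 0.5 * _MIN_TURN_S:
            intervals[speaker].append((t, end))
        if rng.random() < spec.overlap_prob:
            onset = end - min(rng.exponential(spec.overlap_mean_s), 0.9 * (end - t))
        else:
            onset = end + 0.12 + rng.exponential(spec.pause_mean_s)
        speaker = 1 - speaker
        if intervals[speaker]:
            onset = max(onset, intervals[speaker][-1][1] + 0.12)
        t = onset
    return intervals


def _interval_overlap_time(iv_a, iv_b):
    total = 0.0
    for s1, e1 in iv_a:
        for s2, e2 in iv_b:
            total += max(0.0, min(e1, e2) - max(s1, s2))
    return total


def test_overlap_fraction_matches_monte_carlo_oracle():
    """Overlapped-speech fraction agrees with an independently coded
    simulation of the same turn-taking rules (500 replicate draws)."""
    spec = DialogueSpec(duration_s=300.0, overlap_prob=0.2, seed=0)
    n_rep = 500
    impl = np.empty(n_rep)
    for i in range(n_rep):
        rng = np.random.default_rng(1000 + i)
        from dialogtrf.simulate import _sample_turns

        iv_a, iv_b = _sample_turns(spec, rng)
        impl[i] = _interval_overlap_time(iv_a, iv_b) / spec.duration_s
    oracle = np.empty(n_rep)
    for i in range(n_rep):
        rng = np.random.default_rng(50_000 + i)
        iv_a, iv_b = _oracle_turn_taking(spec, rng)
        oracle[i] = _interval_overlap_time(iv_a, iv_b) / spec.duration_s
    se = np.sqrt(impl.var(ddof=1) / n_rep + oracle.var(ddof=1) / n_rep)
    assert abs(impl.mean() - oracle.mean()) < 3 * se


def test_kernel_zero_amplitudes():
    assert np.all(make_kernel([0.1], [0.02], [0.0]) == 0)


def test_kernel_peak_position_and_length():
    k = make_kernel([0.125], [0.015], [1.0])
    assert k.size == 77
    assert np.argmax(k) == round(0.125 * 128) - 1  # lag-16 sample sits at index 15


def test_kernel_peak_outside_window_rejected():
    with pytest.raises(ValueError):
        make_kernel([0.9], [0.02], [1.0])  # beyond 601.6 ms window


def _impulse_gt(n_channels, n_features, lag, seed=0):
    kernels = np.zeros((n_channels, n_features, 77))
    kernels[:, :, lag - 1] = 1.0
    return GroundTruth(kernels=kernels, gain_other=1.0, gain_self=0.0, noise_sd=0.0, seed=seed)


def test_delta_kernel_identity():
    """Unit impulse at lag 5 reproduces the other's summed features delayed
    by 5 samples when noise and self-gain are zero."""
    spec = DialogueSpec(duration_s=30.0, n_channels=2, seed=9)
    a, b = sample_dialogue(spec)
    eeg, _ = synthesize_eeg(a, b, _impulse_gt(2, spec.n_features, lag=5))
    expected = np.zeros_like(eeg[0])
    expected[5:] = b.features.sum(axis=0)[:-5]
    np.testing.assert_allclose(eeg[0], expected, atol=1e-10)
    np.testing.assert_allclose(eeg[1], expected, atol=1e-10)


def test_synthesis_linearity():
    spec = DialogueSpec(duration_s=30.0, n_channels=2, seed=9)
    a, b = sample_dialogue(spec)
    gt = _impulse_gt(2, spec.n_features, lag=3)
    eeg1, _ = synthesize_eeg(a, b, gt)
    b2 = type(b)(b.activity, 2.0 * b.features, b.fs_feature)
    eeg2, _ = synthesize_eeg(a, b2, gt)
    np.testing.assert_allclose(eeg2, 2.0 * eeg1, atol=1e-10)


def test_synthesis_shape_mismatch_rejected():
    spec = DialogueSpec(duration_s=30.0, n_channels=2, seed=9)
    a, b = sample_dialogue(spec)
    short = type(b)(b.activity, b.features[:, :-10], b.fs_feature)
    with pytest.raises(ValueError):
        synthesize_eeg(a, short, _impulse_gt(2, spec.n_features, lag=3))


def test_suppressed_self_speech_uncorrelated_with_eeg():
    """With gain_self = 0 and crosstalk = 0, the EEG carries no linear trace
    of the self features: correlations over S-condition samples stay within
    a permutation null band."""
    session = make_session(duration_s=120.0, n_channels=2, seed=21, snr=3.0)
    mask = condition_mask(session)
    s_idx = np.nonzero(mask.labels == "S")[0]
    env_self = session.track_self.features.mean(axis=0)
    rng = np.random.default_rng(0)
    for lag in (4, 16, 40):
        x = env_self[s_idx - lag]
        y = session.eeg[0, s_idx]
        r_obs = abs(np.corrcoef(x, y)[0, 1])
        null = np.empty(500)
        for j in range(500):
            null[j] = abs(np.corrcoef(x, np.roll(y, rng.integers(100, y.size - 100)))[0, 1])
        assert r_obs < np.quantile(null, 0.995)


def test_pink_noise_spectrum_slope():
    """Spectral shaping exponent 1: power falls ~6 dB per octave."""
    x = pink_noise((4, 2**14), np.random.default_rng(0))
    f = np.fft.rfftfreq(2**14)
    p = (np.abs(np.fft.rfft(x, axis=-1)) ** 2).mean(axis=0)
    band = (f > 0.01) & (f < 0.4)
    slope = np.polyfit(np.log(f[band]), np.log(p[band]), 1)[0]
    assert -1.3 < slope < -0.7


def test_rasterize_midpoint_rule():
    mask = rasterize_intervals([(0.0, 1.0)], 256, 128.0)
    assert mask[:128].all() and not mask[128:].any()
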