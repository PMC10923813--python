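"""Synthetic dyadic-dialog sessions with known ground truth.

This module generates two-speaker conversations (exponential turn-taking with
occasional overlap), 16-band mel-like feature streams at the EEG frame rate,
and EEG obtained by convolving those streams with known per-channel lag
kernels plus 1/f background noise.  Because the response kernels, the gain on
other-produced speech, the gain on self-produced speech (0 = full
speech-induced suppression) and the microphone crosstalk are all specified
explicitly, every downstream stage — segmentation, encoding, permutation
significance, group statistics and phase locking — can be validated against
ground truth without any recorded data.

The generator is an artifact of this package: the study it emulates analyzed
recorded dialogs and states no generative model.  Defaults are chosen to be
realistic for task-oriented dialog (turns of ~1.5 s, pauses of ~0.5 s,
sessions of a few minutes) and are documented in ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "DialogueSpec",
    "SpeechTrack",
    "GroundTruth",
    "InvalidSpecError",
    "sample_dialogue",
    "make_kernel",
    "default_kernel_bank",
    "synthesize_eeg",
    "mic_features",
    "pink_noise",
    "simulate_session",
    "Session",
]

N_LAGS_DEFAULT = 77


class InvalidSpecError(ValueError):
    """Raised when a DialogueSpec violates its invariants."""


@dataclass(frozen=True)
class DialogueSpec:
    """Parameters of one synthetic dialog session.

    Turn and pause lengths are exponential (memoryless turn-taking); with
    probability ``overlap_prob`` a turn onset overlaps the other speaker's
    ongoing turn, producing Both-speaking intervals.
    """

    duration_s: float = 300.0
    turn_mean_s: float = 1.5
    pause_mean_s: float = 0.5
    overlap_prob: float = 0.2
    overlap_mean_s: float = 0.4
    n_channels: int = 8
    n_features: int = 16
    fs_feature: int = 128
    fs_audio: int = 16000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise InvalidSpecError("duration_s must be positive")
        if not (0.0 <= self.overlap_prob <= 1.0):
            raise InvalidSpecError("overlap_prob must lie in [0, 1]")
        if self.fs_feature <= 0 or self.fs_audio <= 0:
            raise InvalidSpecError("sampling rates must be positive")
        if self.fs_audio % self.fs_feature:
            raise InvalidSpecError("fs_audio must be an integer multiple of fs_feature")
        if self.turn_mean_s <= 0 or self.pause_mean_s <= 0:
            raise InvalidSpecError("turn and pause means must be positive")
        if self.n_channels < 1 or self.n_features < 1:
            raise InvalidSpecError("n_channels and n_features must be >= 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fs_feature))


@dataclass
class SpeechTrack:
    """One speaker's activity intervals and feature stream.

    ``activity`` holds sorted, non-overlapping ``[start_s, end_s)`` speech
    intervals; ``features`` (n_features x n_frames) is zero outside them.
    """

    activity: list[tuple[float, float]]
    features: np.ndarray
    fs_feature: int
    audio: np.ndarray | None = None
    fs_audio: int | None = None

    @property
    def n_frames(self) -> int:
        return self.features.shape[1]

    def envelope(self) -> np.ndarray:
        """Broadband envelope proxy: mean over feature bands, shape (1, n_frames)."""
        return self.features.mean(axis=0, keepdims=True)

    def activity_mask(self) -> np.ndarray:
        """Boolean per-frame speech mask (frame-midpoint rasterization)."""
        return rasterize_intervals(self.activity, self.n_frames, self.fs_feature)


@dataclass
class GroundTruth:
    """Generative parameters of the synthetic EEG.

    ``gain_self = 0`` encodes full speech-induced suppression; ``crosstalk``
    is the attenuated leak of the other speaker's features into one's own
    microphone channel.
    """

    kernels: np.ndarray  # (n_channels, n_features, n_lags)
    gain_other: float = 1.0
    gain_self: float = 0.0
    crosstalk: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.kernels = np.asarray(self.kernels, dtype=float)
        if self.kernels.ndim != 3:
            raise ValueError("kernels must have shape (n_channels, n_features, n_lags)")
        if self.gain_other < 0 or self.gain_self < 0:
            raise ValueError("gains must be non-negative")
        if not (0.0 <= self.crosstalk < 1.0):
            raise ValueError("crosstalk must lie in [0, 1)")

    @property
    def n_lags(self) -> int:
        return self.kernels.shape[2]


def rasterize_intervals(
    intervals: list[tuple[float, float]], n_frames: int, fs: float
) -> np.ndarray:
    """Frame t is active iff its midpoint (t + 0.5)/fs falls in an interval."""
    mask = np.zeros(n_frames, dtype=bool)
    mid = (np.arange(n_frames) + 0.5) / fs
    for start, end in intervals:
        mask |= (mid >= start) & (mid < end)
    return mask


# ---------------------------------------------------------------------------
# turn-taking
# ---------------------------------------------------------------------------

_MIN_TURN_S = 0.3  # floor on turn length so every turn is rasterizable
_IPU_GAP_S = 0.12  # same-speaker gap kept > the 100 ms pause rule


def _sample_turns(
    spec: DialogueSpec, rng: np.random.Generator
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Alternating exponential turns; overlapped onsets with prob overlap_prob."""
    intervals: tuple[list, list] = ([], [])
    speaker = int(rng.integers(2))
    t = float(rng.exponential(spec.pause_mean_s))
    while t < spec.duration_s:
        length = _MIN_TURN_S + rng.exponential(spec.turn_mean_s)
        end = min(t + length, spec.duration_s)
        if end - t >= 0.5 * _MIN_TURN_S:
            intervals[speaker].append((t, end))
        # schedule the next speaker's onset
        if rng.random() < spec.overlap_prob:
            overlap = min(rng.exponential(spec.overlap_mean_s), 0.9 * (end - t))
            onset = end - overlap
        else:
            onset = end + _IPU_GAP_S + rng.exponential(spec.pause_mean_s)
        speaker = 1 - speaker
        prev = intervals[speaker][-1][1] if intervals[speaker] else -np.inf
        t = max(onset, prev + _IPU_GAP_S)
    return intervals[0], intervals[1]


def _speech_features(
    spec: DialogueSpec, mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Band-correlated amplitude-modulated noise profiles, zero outside speech.

    A shared syllabic-rate modulator (smoothed rectified noise, < ~8 Hz)
    drives all bands, scaled by slowly varying per-band gains, emulating the
    band-correlated structure of real speech spectrograms.
    """
    n = mask.size
    fs = spec.fs_feature

    def smooth(x: np.ndarray, cutoff_hz: float) -> np.ndarray:
        # moving-average smoothing with ~cutoff_hz bandwidth
        w = max(1, int(round(fs / (2 * cutoff_hz))))
        kernel = np.ones(w) / w
        return fftconvolve(x, kernel, mode="same")

    modulator = np.abs(smooth(rng.standard_normal(n), 6.0)) + 0.05
    band_gain = 0.5 + rng.random(spec.n_features)  # static spectral tilt
    band_mod = 1.0 + 0.3 * smooth(
        rng.standard_normal((spec.n_features, n)).ravel(), 4.0
    ).reshape(spec.n_features, n)
    feats = band_gain[:, None] * modulator[None, :] * np.abs(band_mod)
    feats[:, ~mask] = 0.0
    return feats


def sample_dialogue(
    spec: DialogueSpec, rng: np.random.Generator | None = None
) -> tuple[SpeechTrack, SpeechTrack]:
    """Draw one dyadic dialog: two speech tracks with activity and features.

    Deterministic given ``spec.seed`` (or an explicit ``rng``).  With
    ``overlap_prob = 0`` the two activity masks are never simultaneously true.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    acts = _sample_turns(spec, rng)
    tracks = []
    for intervals in acts:
        mask = rasterize_intervals(intervals, spec.n_frames, spec.fs_feature)
        feats = _speech_features(spec, mask, rng)
        tracks.append(SpeechTrack(intervals, feats, spec.fs_feature))
    return tracks[0], tracks[1]


# ---------------------------------------------------------------------------
# response kernels and EEG synthesis
# ---------------------------------------------------------------------------


def make_kernel(
    peak_lags_s,
    widths_s,
    amplitudes,
    n_lags: int = N_LAGS_DEFAULT,
    fs: float = 128.0,
) -> np.ndarray:
    """Sum-of-Gaussian lag kernel sampled at lags 1..n_lags (in samples).

    Shapes mimic auditory evoked responses (e.g. a negative deflection near
    100 ms followed by a positive one near 200 ms).  Deterministic.
    """
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    peak_lags_s = np.atleast_1d(np.asarray(peak_lags_s, dtype=float))
    widths_s = np.atleast_1d(np.asarray(widths_s, dtype=float))
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    if not (peak_lags_s.size == widths_s.size == amplitudes.size):
        raise ValueError("peak_lags_s, widths_s, amplitudes must have equal length")
    lag_s = np.arange(1, n_lags + 1) / fs
    if np.any(peak_lags_s < lag_s[0] - 1e-12) or np.any(peak_lags_s > lag_s[-1] + 1e-12):
        raise ValueError("peak lags must lie within the lag window")
    k = np.zeros(n_lags)
    for p, w, a in zip(peak_lags_s, widths_s, amplitudes):
        k += a * np.exp(-0.5 * ((lag_s - p) / w) ** 2)
    return k


def default_kernel_bank(
    n_channels: int,
    n_features: int,
    n_lags: int = N_LAGS_DEFAULT,
    fs: float = 128.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Evoked-response-like kernels, amplitude varying smoothly over channels."""
    if rng is None:
        rng = np.random.default_rng(0)
    base = make_kernel([0.100, 0.210], [0.025, 0.045], [-1.0, 0.7], n_lags, fs)
    chan_gain = 0.6 + 0.8 * rng.random(n_channels)
    # mid bands respond most, like the speech-informative mel range
    band = np.arange(n_features)
    band_gain = 0.4 + np.exp(-0.5 * ((band - n_features / 2) / (n_features / 3)) ** 2)
    kernels = chan_gain[:, None, None] * band_gain[None, :, None] * base[None, None, :]
    kernels += 0.05 * rng.standard_normal(kernels.shape) * np.abs(base).max()
    return kernels


def pink_noise(
    shape: tuple[int, ...], rng: np.random.Generator, exponent: float = 1.0
) -> np.ndarray:
    """1/f^exponent (power) noise via spectral shaping, unit SD per row."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _causal_response(features: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Per channel: sum over features of the causal lag-1..L convolution."""
    n_channels, n_features, n_lags = kernels.shape
    n = features.shape[1]
    out = np.zeros((n_channels, n))
    for c in range(n_channels):
        for f in range(n_features):
            # lag 0 coefficient is zero: kernel applies to strictly past frames
            full = fftconvolve(features[f], np.concatenate(([0.0], kernels[c, f])))
            out[c] += full[:n]
    return out


def mic_features(
    own: SpeechTrack, other: SpeechTrack, crosstalk: float
) -> np.ndarray:
    """Features recorded at one speaker's microphone: own speech plus an
    attenuated leak of the other speaker's speech."""
    if own.features.shape != other.features.shape:
        raise ValueError("tracks must share feature shape")
    return own.features + crosstalk * other.features


def synthesize_eeg(
    self_track: SpeechTrack,
    other_track: SpeechTrack,
    gt: GroundTruth,
    snr: float | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Generate EEG for the participant who produced ``self_track``.

    y_c = gain_other * sum_f (k_cf * x_other_f) + gain_self * sum_f (k_cf * x_self_f)
          + noise_sd * pink_noise

    Convolution is strictly causal (lag >= 1 sample).  If ``snr`` is given,
    the noise SD is rescaled per channel so that
    var(deterministic part)/var(noise) = snr, and the effective ground truth
    is returned alongside the data.  Deterministic given ``gt.seed``.
    """
    if self_track.features.shape != other_track.features.shape:
        raise ValueError("tracks must share fs_feature and length")
    if self_track.features.shape[0] != gt.kernels.shape[1]:
        raise ValueError("feature count does not match kernel bank")
    rng = np.random.default_rng(gt.seed)
    signal = gt.gain_other * _causal_response(other_track.features, gt.kernels)
    if gt.gain_self != 0.0:
        signal += gt.gain_self * _causal_response(self_track.features, gt.kernels)
    n_channels, n = signal.shape
    noise = pink_noise((n_channels, n), rng)
    if snr is not None:
        sig_sd = signal.std(axis=1, keepdims=True)
        sig_sd[sig_sd == 0] = 1.0
        noise_sd = (sig_sd / np.sqrt(snr)).ravel()
        eeg = signal + noise * noise_sd[:, None]
        gt = replace(gt, noise_sd=float(noise_sd.mean()))
    else:
        eeg = signal + gt.noise_sd * noise
    return eeg, gt


# ---------------------------------------------------------------------------
# whole sessions
# ---------------------------------------------------------------------------


@dataclass
class Session:
    """One simulated session seen from participant A's perspective.

    A's EEG responds to B's speech with ``gain_other`` and to A's own speech
    with ``gain_self``; microphone features include crosstalk.
    """

    spec: DialogueSpec
    gt: GroundTruth
    track_self: SpeechTrack  # participant A's own speech
    track_other: SpeechTrack  # the partner's speech
    eeg: np.ndarray  # (n_channels, n_frames) at fs_feature
    mic_self: np.ndarray = field(default=None)  # type: ignore[assignment]
    mic_other: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mic_self is None:
            self.mic_self = mic_features(self.track_self, self.track_other, self.gt.crosstalk)
        if self.mic_other is None:
            self.mic_other = mic_features(self.track_other, self.track_self, self.gt.crosstalk)


def simulate_session(
    spec: DialogueSpec,
    gt: GroundTruth | None = None,
    snr: float | None = None,
) -> Session:
    """Sample a dialog and synthesize one participant's EEG from it."""
    track_a, track_b = sample_dialogue(spec)
    if gt is None:
        rng = np.random.default_rng(spec.seed + 1)
        kernels = default_kernel_bank(spec.n_channels, spec.n_features, rng=rng)
        gt = GroundTruth(kernels=kernels, seed=spec.seed + 2)
    eeg, gt_eff = synthesize_eeg(track_a, track_b, gt, snr=snr)
    return Session(spec=spec, gt=gt_eff, track_self=track_a, track_other=track_b, eeg=eeg)
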