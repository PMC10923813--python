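"""Stimulus feature extraction at the EEG frame rate.

Speech audio at 16 kHz is reduced to encoding-model inputs computed on
non-overlapping windows of 125 audio samples, giving exactly 128 feature
frames per second — the same rate as the downsampled EEG.  Windowing is
strictly causal: frame k uses only audio samples ``[125k, 125(k+1))``, so no
feature frame contains information from later audio.

Two features are provided: a 16-band mel spectrogram (triangular Slaney-style
filters up to 8 kHz, power scale, per-band min-max normalized) and the
broadband envelope (modulus of the analytic signal, window-averaged, min-max
normalized to [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import correlate, hilbert, resample_poly

__all__ = [
    "FeatureSeries",
    "RateError",
    "compute_mel_spectrogram",
    "compute_envelope",
    "sync_by_crosscorr",
    "mel_filterbank",
    "read_wav",
    "resample_to_16k",
]

FRAME_SAMPLES = 125
AUDIO_FS = 16000
FRAME_RATE = AUDIO_FS // FRAME_SAMPLES  # 128 Hz
N_MEL = 16
FMAX = 8000.0
NFFT = 128  # 125-sample windows zero-padded to 128


class RateError(ValueError):
    """Audio is not at the required 16 kHz rate (caller must resample)."""


@dataclass
class FeatureSeries:
    """A stimulus feature stream: (n_features, n_frames) at ``fs`` Hz."""

    name: str
    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# mel filterbank (Slaney convention: linear below 1 kHz, log above;
# area-normalized triangles)
# ---------------------------------------------------------------------------

_F_SP = 200.0 / 3.0
_LOG_STEP = np.log(6.4) / 27.0
_BREAK_HZ = 1000.0
_BREAK_MEL = _BREAK_HZ / _F_SP


def hz_to_mel(f):
    f = np.asarray(f, dtype=float)
    mel = f / _F_SP
    log_region = f >= _BREAK_HZ
    mel = np.where(log_region, _BREAK_MEL + np.log(np.maximum(f, 1e-12) / _BREAK_HZ) / _LOG_STEP, mel)
    return mel


def mel_to_hz(m):
    m = np.asarray(m, dtype=float)
    f = m * _F_SP
    log_region = m >= _BREAK_MEL
    return np.where(log_region, _BREAK_HZ * np.exp(_LOG_STEP * (m - _BREAK_MEL)), f)


def mel_filterbank(
    n_mels: int = N_MEL,
    n_fft: int = NFFT,
    fs: float = AUDIO_FS,
    fmin: float = 0.0,
    fmax: float = FMAX,
) -> np.ndarray:
    """Triangular area-normalized mel filterbank, shape (n_mels, n_fft//2+1)."""
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    fb = np.zeros((n_mels, fft_freqs.size))
    for i in range(n_mels):
        lo, ctr, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
        fb[i] *= 2.0 / (hi - lo)  # area normalization
    return fb


def _frame(audio: np.ndarray) -> np.ndarray:
    """Split audio into non-overlapping 125-sample rows (tail discarded)."""
    audio = np.asarray(audio, dtype=float).ravel()
    n_frames = audio.size // FRAME_SAMPLES
    return audio[: n_frames * FRAME_SAMPLES].reshape(n_frames, FRAME_SAMPLES)


def _minmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    lo = x.min(axis=axis, keepdims=True)
    hi = x.max(axis=axis, keepdims=True)
    span = hi - lo
    span[span == 0] = 1.0  # constant rows stay at 0
    return (x - lo) / span


def compute_mel_spectrogram(
    audio: np.ndarray, fs: float = AUDIO_FS, normalize: bool = True
) -> FeatureSeries:
    """16-band mel power spectrogram at 128 Hz from 16 kHz mono audio.

    Each frame is one 125-sample window zero-padded to 128 for the FFT; with
    ``normalize`` each band is min-max scaled to [0, 1] like the envelope
    (the scaling uses the whole recording, so pass ``normalize=False`` when
    strict per-frame causality matters more than the model input contract).
    """
    if fs != AUDIO_FS:
        raise RateError(f"audio must be at {AUDIO_FS} Hz, got {fs}")
    frames = _frame(audio)
    if frames.size == 0:
        return FeatureSeries("spectrogram", np.zeros((N_MEL, 0)), FRAME_RATE)
    spectrum = np.fft.rfft(frames, n=NFFT, axis=1)
    power = np.abs(spectrum) ** 2
    mel = mel_filterbank() @ power.T  # (n_mels, n_frames)
    return FeatureSeries("spectrogram", _minmax(mel) if normalize else mel, FRAME_RATE)


def compute_envelope(
    audio: np.ndarray, fs: float = AUDIO_FS, normalize: bool = True
) -> FeatureSeries:
    """Analytic-signal envelope averaged over 125-sample windows, in [0, 1]."""
    if fs != AUDIO_FS:
        raise RateError(f"audio must be at {AUDIO_FS} Hz, got {fs}")
    audio = np.asarray(audio, dtype=float).ravel()
    if audio.size == 0:
        return FeatureSeries("envelope", np.zeros((1, 0)), FRAME_RATE)
    env = np.abs(hilbert(audio))
    frames = _frame(env)
    if frames.size == 0:
        return FeatureSeries("envelope", np.zeros((1, 0)), FRAME_RATE)
    coarse = frames.mean(axis=1)[None, :]
    return FeatureSeries("envelope", _minmax(coarse) if normalize else coarse, FRAME_RATE)


def sync_by_crosscorr(reference: np.ndarray, delayed_copy: np.ndarray) -> int:
    """Integer lag L maximizing cross-correlation: delayed_copy[t] ~ reference[t-L].

    Shifting ``delayed_copy`` by -L aligns it with ``reference``.
    """
    reference = np.asarray(reference, dtype=float).ravel()
    delayed_copy = np.asarray(delayed_copy, dtype=float).ravel()
    if np.ptp(reference) == 0 or np.ptp(delayed_copy) == 0:
        raise ValueError("undefined lag: constant input signal")
    a = delayed_copy - delayed_copy.mean()
    b = reference - reference.mean()
    cc = correlate(a, b, mode="full")
    return int(np.argmax(cc) - (b.size - 1))


def read_wav(path) -> tuple[int, np.ndarray]:
    """Read a PCM WAV file as (fs, float mono waveform in [-1, 1])."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return int(fs), data.astype(float)


def resample_to_16k(audio: np.ndarray, fs: int) -> np.ndarray:
    """Polyphase resampling to the 16 kHz analysis rate."""
    if fs == AUDIO_FS:
        return np.asarray(audio, dtype=float)
    from math import gcd

    g = gcd(int(fs), AUDIO_FS)
    return resample_poly(np.asarray(audio, dtype=float), AUDIO_FS // g, int(fs) // g)
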