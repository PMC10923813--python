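"""Lagged phase-locking between the speech envelope and EEG channels.

Both signals are band-passed to 4-8 Hz (theta, the syllabic rate of speech),
their instantaneous phases extracted with the Hilbert transform, and the
phase-locking value computed as the modulus of the mean complex unit vector
of phase differences:

    |PLV(tau)| = | (1/n) sum_t exp(i (theta_env(t - tau) - theta_eeg(t))) |

Positive lags delay the envelope relative to the EEG, i.e. the brain follows
the audio; negative lags would require the EEG to precede the stimulus.  The
scan covers -200..400 ms in one-sample steps (7.8125 ms at 128 Hz) plus the
exact interval endpoints, applied as fractional delays of the band-limited
analytic signal (exact via FFT phase rotation).  All samples of a dialog
condition are pooled as one single trial; samples near segment boundaries
(within one period of the band's low edge) are dropped to limit filter edge
artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from mne.filter import filter_data
from scipy.signal import hilbert

from .features import FeatureSeries
from .preprocess import BANDS, EEGRecording

__all__ = [
    "PLVResult",
    "compute_plv",
    "plv_lag_scan",
    "default_lag_grid",
]

PLV_BAND = BANDS["Theta"]  # 4-8 Hz for both envelope and EEG


def compute_plv(theta_env: np.ndarray, theta_eeg: np.ndarray) -> float:
    """|PLV| of two phase series: modulus of the mean phase-difference phasor."""
    theta_env = np.asarray(theta_env, float).ravel()
    theta_eeg = np.asarray(theta_eeg, float).ravel()
    if theta_env.size == 0 or theta_env.size != theta_eeg.size:
        raise ValueError("phase series must be non-empty and equal length")
    return float(np.abs(np.mean(np.exp(1j * (theta_env - theta_eeg)))))


def default_lag_grid(fs: float = 128.0, start_ms: float = -200.0, stop_ms: float = 400.0) -> np.ndarray:
    """Sample-aligned lags covering (start, stop) plus the exact endpoints."""
    step = 1000.0 / fs
    k0 = int(np.floor(start_ms / step)) + 1
    k1 = int(np.ceil(stop_ms / step)) - 1
    interior = np.arange(k0, k1 + 1) * step
    return np.unique(np.concatenate(([start_ms], interior, [stop_ms])))


def _theta_analytic(x: np.ndarray, fs: float) -> np.ndarray:
    lo, hi = PLV_BAND
    filtered = filter_data(
        np.atleast_2d(np.asarray(x, float)),
        sfreq=fs,
        l_freq=lo,
        h_freq=hi,
        l_trans_bandwidth=max(0.25 * lo, 0.1),
        h_trans_bandwidth=max(0.25 * lo, 0.1),
        fir_window="hamming",
        fir_design="firwin",
        phase="zero",
        pad="edge",
        verbose=False,
    )
    return hilbert(filtered, axis=-1)


def _fractional_delay(analytic: np.ndarray, delay_samples: float) -> np.ndarray:
    """Delay a (band-limited) analytic signal by a possibly fractional lag."""
    n = analytic.shape[-1]
    spec = np.fft.fft(analytic, axis=-1)
    freqs = np.fft.fftfreq(n)
    return np.fft.ifft(spec * np.exp(-2j * np.pi * freqs * delay_samples), axis=-1)


def _guarded_samples(
    condition_samples: np.ndarray, n_frames: int, guard: int, max_lag: int
) -> np.ndarray:
    """Drop samples within ``guard`` frames of a segment edge and within
    ``max_lag`` frames of the recording edges."""
    idx = np.unique(np.asarray(condition_samples, dtype=int))
    if idx.size == 0:
        return idx
    keep = []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [idx.size]))
    for s, e in zip(starts, ends):
        seg = idx[s:e]
        if seg.size > 2 * guard:
            keep.append(seg[guard : seg.size - guard])
    if not keep:
        return np.empty(0, dtype=int)
    out = np.concatenate(keep)
    return out[(out >= max_lag) & (out < n_frames - max_lag)]


@dataclass
class PLVResult:
    """Per-channel |PLV| as a function of stimulus-EEG lag."""

    lags_ms: np.ndarray
    plv: np.ndarray  # (n_channels, n_lags) in [0, 1]
    peak_lag_ms: float
    n: int
    condition: str = ""

    def channel_average(self) -> np.ndarray:
        return self.plv.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        ch, lag = np.meshgrid(
            np.arange(self.plv.shape[0]), self.lags_ms, indexing="ij"
        )
        return pd.DataFrame(
            {
                "channel": ch.ravel(),
                "lag_ms": lag.ravel(),
                "plv": self.plv.ravel(),
                "condition": self.condition,
            }
        )


def plv_lag_scan(
    env,
    eeg: EEGRecording,
    condition_samples,
    lags_ms: np.ndarray | None = None,
    guard_s: float = 0.25,
    condition: str = "",
) -> PLVResult:
    """Scan |PLV| between the envelope and every EEG channel over lags.

    ``env`` is a FeatureSeries or 1-D envelope at the EEG rate; both signals
    are band-passed 4-8 Hz (zero-phase, identical design, so latencies are
    not filter-shifted) before phase extraction.  ``condition_samples`` pools
    the frames of one dialog condition as a single trial.
    """
    env_vals = env.values[0] if isinstance(env, FeatureSeries) else np.asarray(env, float).ravel()
    fs = float(env.fs) if isinstance(env, FeatureSeries) else float(eeg.fs)
    if isinstance(env, FeatureSeries) and env.fs != eeg.fs:
        raise ValueError("envelope and EEG must share the sampling rate")
    if env_vals.size != eeg.n_samples:
        raise ValueError("envelope and EEG must share the frame axis")
    if lags_ms is None:
        lags_ms = default_lag_grid(fs)
    lags_ms = np.asarray(lags_ms, float)

    a_env = _theta_analytic(env_vals, fs)[0]
    a_eeg = _theta_analytic(eeg.data, fs)
    unit_eeg = a_eeg / np.maximum(np.abs(a_eeg), 1e-300)

    max_lag = int(np.ceil(np.abs(lags_ms).max() / 1000.0 * fs)) + 1
    idx = _guarded_samples(condition_samples, env_vals.size, int(round(guard_s * fs)), max_lag)
    if idx.size < fs / PLV_BAND[0]:
        warnings.warn(
            f"only {idx.size} samples after edge guarding: less than one "
            f"cycle of {PLV_BAND[0]} Hz; PLV is unreliable"
        )
    if idx.size == 0:
        raise ValueError("no usable samples for the requested condition")

    plv = np.empty((eeg.n_channels, lags_ms.size))
    conj_eeg = np.conj(unit_eeg[:, idx])
    for i, lag in enumerate(lags_ms):
        shifted = _fractional_delay(a_env, lag / 1000.0 * fs)
        unit_env = shifted[idx] / np.maximum(np.abs(shifted[idx]), 1e-300)
        plv[:, i] = np.abs((conj_eeg * unit_env[None, :]).mean(axis=1))
    peak = float(lags_ms[int(np.argmax(plv.mean(axis=0)))])
    return PLVResult(lags_ms=lags_ms, plv=plv, peak_lag_ms=peak, n=int(idx.size), condition=condition)
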