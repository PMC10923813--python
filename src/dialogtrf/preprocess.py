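"""EEG band filtering, standardization, downsampling and re-referencing.

Band definitions follow the classical EEG rhythms: Delta 1-4 Hz, Theta
4-8 Hz, Alpha 8-13 Hz, Low Beta 13-19 Hz and a broad 0.1-40 Hz band.  Filters
are window-method FIR (hamming), either minimum-phase causal — so that no
filtered sample depends on future input, at the cost of a small group delay —
or zero-phase, with edge-value padding.  Downsampling to the 128 Hz analysis
rate applies an anti-alias FIR low-pass before integer sub-sampling, and
channels are z-scored afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from mne.filter import filter_data
from scipy.signal import decimate

__all__ = [
    "BANDS",
    "EEGRecording",
    "bandpass_band",
    "standardize_and_downsample",
    "rereference_average",
    "apply_ica_hook",
]

BANDS: dict[str, tuple[float, float]] = {
    "Delta": (1.0, 4.0),
    "Theta": (4.0, 8.0),
    "Alpha": (8.0, 13.0),
    "LowBeta": (13.0, 19.0),
    "Broad": (0.1, 40.0),
}


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is (n_channels, n_samples) at ``fs`` Hz."""

    data: np.ndarray
    fs: float
    band: str = "raw"
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.channel_names is None:
            self.channel_names = [f"ch{i:03d}" for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _transition_bandwidth(low_edge: float) -> float:
    # 25% of the band's lower edge, floored so broad-band filters stay
    # realizable on minute-scale recordings
    return max(0.25 * low_edge, 0.1)


def bandpass_band(
    rec: EEGRecording,
    band: str,
    phase: str = "causal_minimum_phase",
) -> EEGRecording:
    """Filter into a named EEG band.

    ``phase='causal_minimum_phase'`` uses a minimum-phase FIR (non-negative
    group delay: no output before input onset); ``phase='zero_phase'`` uses
    forward-backward linear-phase filtering (no delay).
    """
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; choose from {sorted(BANDS)}")
    if phase not in ("causal_minimum_phase", "zero_phase"):
        raise ValueError("phase must be 'causal_minimum_phase' or 'zero_phase'")
    lo, hi = BANDS[band]
    if rec.fs <= 2 * hi:
        raise ValueError(f"fs={rec.fs} too low for band {band} (upper edge {hi} Hz)")
    tb = _transition_bandwidth(lo)
    out = filter_data(
        rec.data,
        sfreq=rec.fs,
        l_freq=lo,
        h_freq=hi,
        l_trans_bandwidth=tb,
        h_trans_bandwidth=tb,
        fir_window="hamming",
        fir_design="firwin",
        phase="minimum" if phase == "causal_minimum_phase" else "zero",
        pad="edge",
        verbose=False,
    )
    return replace(rec, data=out, band=band)


def standardize_and_downsample(rec: EEGRecording, target_fs: float) -> EEGRecording:
    """Anti-alias decimate to ``target_fs`` and z-score each channel.

    ``rec.fs`` must be an integer multiple of ``target_fs``.  The output
    length is floor(n_samples * target_fs / fs) and each channel has mean 0
    and SD 1 exactly (population convention).
    """
    ratio = rec.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"fs={rec.fs} is not an integer multiple of target_fs={target_fs}")
    q = int(round(ratio))
    n_out = int(rec.data.shape[1] * target_fs // rec.fs)
    if q > 1:
        data = decimate(rec.data, q, ftype="fir", axis=1, zero_phase=True)[:, :n_out]
    else:
        data = rec.data[:, :n_out].copy()
    mean = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return replace(rec, data=(data - mean) / sd, fs=float(target_fs))


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the instantaneous average of all electrodes."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))


def apply_ica_hook(
    rec: EEGRecording,
    hook: Callable[[EEGRecording], EEGRecording] | None = None,
) -> EEGRecording:
    """Pass-through artifact-removal hook for real-data workflows.

    Component-based artifact rejection requires expert supervision and is not
    re-implemented here; supply a callable to plug in an external cleaner.
    """
    return rec if hook is None else hook(rec)
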