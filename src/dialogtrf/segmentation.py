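"""From speech interval annotations to dialog conditions and training samples.

An inter-pausal unit (IPU) is a maximal speech segment from one speaker
bounded by pauses longer than 100 ms: annotated bursts separated by gaps of
at most 100 ms are merged.  From the two speakers' IPUs, every feature frame
gets exactly one dialog condition from one participant's perspective:

* ``S``      — only the participant themself is speaking
* ``E``      — only the partner (external speech)
* ``B``      — both speaking (analyzed as E|B with the partner's microphone
               features, or S|B with one's own)
* ``Silence``— neither

Training samples for the lagged encoding model are frame indices ``t`` whose
entire trailing window ``[t - w + 1, t]`` carries the requested condition
(overlapping sliding windows with a one-frame step).

Intervals are half-open ``[start_s, end_s)`` seconds; frame ``t`` covers
``[t/fs, (t+1)/fs)`` and counts as speech when its midpoint lies in an IPU.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IPUList",
    "ConditionMask",
    "CONDITIONS",
    "detect_ipus",
    "label_conditions",
    "extract_training_samples",
    "read_intervals_csv",
    "write_intervals_csv",
    "read_textgrid",
]

CONDITIONS = ("Silence", "S", "E", "B")
MIN_PAUSE_S = 0.1


@dataclass
class IPUList:
    """Sorted, non-overlapping IPUs for one speaker; gaps all > min_pause_s."""

    speaker: str
    intervals: list[tuple[float, float]] = field(default_factory=list)

    def duration(self) -> float:
        return float(sum(e - s for s, e in self.intervals))


def detect_ipus(
    raw_intervals,
    min_pause_s: float = MIN_PAUSE_S,
    speaker: str = "",
) -> IPUList:
    """Merge speech bursts separated by pauses of at most ``min_pause_s``.

    A strictly-greater gap separates IPUs.  Unsorted or overlapping input is
    normalized first; negative times are an error.
    """
    intervals = [(float(s), float(e)) for s, e in raw_intervals]
    if any(s < 0 or e < s for s, e in intervals):
        raise ValueError("intervals must have 0 <= start <= end")
    intervals.sort()
    merged: list[tuple[float, float]] = []
    # small tolerance so a nominal 100 ms pause (e.g. 1.1 - 1.0 in floats)
    # still counts as <= the threshold
    eps = 1e-9
    for s, e in intervals:
        if merged and s - merged[-1][1] <= min_pause_s + eps:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return IPUList(speaker=speaker, intervals=merged)


@dataclass
class ConditionMask:
    """Per-frame dialog condition labels from one participant's perspective."""

    labels: np.ndarray  # array of strings in CONDITIONS
    fs: float

    @property
    def n_frames(self) -> int:
        return self.labels.size

    def counts(self) -> dict[str, int]:
        vals, cnts = np.unique(self.labels, return_counts=True)
        out = {c: 0 for c in CONDITIONS}
        out.update(dict(zip(vals.tolist(), cnts.tolist())))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(self.n_frames), "condition": self.labels}
        )


def _midpoint_mask(ipus: IPUList, n_frames: int, fs: float) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    mid = (np.arange(n_frames) + 0.5) / fs
    for s, e in ipus.intervals:
        mask |= (mid >= s) & (mid < e)
    return mask


def label_conditions(
    self_ipus: IPUList, other_ipus: IPUList, n_frames: int, fs: float
) -> ConditionMask:
    """Assign S / E / B / Silence to every frame."""
    own = _midpoint_mask(self_ipus, n_frames, fs)
    ext = _midpoint_mask(other_ipus, n_frames, fs)
    labels = np.full(n_frames, "Silence", dtype=object)
    labels[own & ~ext] = "S"
    labels[~own & ext] = "E"
    labels[own & ext] = "B"
    return ConditionMask(labels=labels.astype(str), fs=fs)


def extract_training_samples(
    mask: ConditionMask, condition: str, window_frames: int = 77
) -> np.ndarray:
    """Indices t whose trailing window [t-w+1, t] is all in ``condition``.

    A run of L >= w condition frames yields L - w + 1 valid indices.
    """
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    good = (mask.labels == condition).astype(int)
    run = np.convolve(good, np.ones(window_frames, dtype=int), mode="full")[
        : good.size
    ]
    return np.nonzero(run == window_frames)[0]


# ---------------------------------------------------------------------------
# interval IO
# ---------------------------------------------------------------------------


def read_intervals_csv(path) -> dict[str, list[tuple[float, float]]]:
    """Read a (speaker, start_s, end_s) table into per-speaker interval lists."""
    df = pd.read_csv(path)
    out: dict[str, list[tuple[float, float]]] = {}
    for spk, grp in df.groupby("speaker"):
        out[str(spk)] = list(zip(grp["start_s"].astype(float), grp["end_s"].astype(float)))
    return out


def write_intervals_csv(path, intervals_by_speaker: dict[str, list[tuple[float, float]]]) -> None:
    rows = [
        {"speaker": spk, "start_s": s, "end_s": e}
        for spk, ivs in intervals_by_speaker.items()
        for s, e in ivs
    ]
    pd.DataFrame(rows, columns=["speaker", "start_s", "end_s"]).to_csv(path, index=False)


_TG_ITEM = re.compile(r'item\s*\[\d+\]\s*:', re.IGNORECASE)
_TG_FIELD = re.compile(r'(\w+)\s*=\s*(".*?"|[-+0-9.eE]+)')


def read_textgrid(path, tiers: list[str] | None = None) -> dict[str, list[tuple[float, float]]]:
    """Minimal Praat TextGrid (long text format) interval-tier reader.

    Returns non-empty-text intervals per tier name.  Only interval tiers are
    parsed; point tiers are ignored.
    """
    text = open(path, encoding="utf-8", errors="replace").read()
    out: dict[str, list[tuple[float, float]]] = {}
    chunks = _TG_ITEM.split(text)[1:]
    for chunk in chunks:
        fields = _TG_FIELD.findall(chunk)
        kv: dict[str, list[str]] = {}
        for k, v in fields:
            kv.setdefault(k, []).append(v.strip('"'))
        if kv.get("class", [""])[0] != "IntervalTier":
            continue
        name = kv.get("name", ["?"])[0]
        if tiers is not None and name not in tiers:
            continue
        xmins = [float(v) for v in kv.get("xmin", [])][1:]  # first is tier xmin
        xmaxs = [float(v) for v in kv.get("xmax", [])][1:]
        texts = kv.get("text", [])
        ivs = [
            (lo, hi)
            for lo, hi, tx in zip(xmins, xmaxs, texts)
            if tx.strip() not in ("", "#")
        ]
        out[name] = ivs
    return out
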