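"""HDF5 / CSV persistence for simulated sessions and analysis outputs."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .segmentation import write_intervals_csv
from .simulate import DialogueSpec, GroundTruth, Session, SpeechTrack

__all__ = ["save_session", "load_session", "save_trf_h5", "write_json"]


def _write_intervals(grp: h5py.Group, name: str, intervals) -> None:
    arr = np.array(intervals, dtype=float).reshape(-1, 2)
    grp.create_dataset(name, data=arr)


def save_session(path, session: Session) -> None:
    """Write a session (features, intervals, EEG, ground truth, seed) to HDF5
    plus a sibling ``*.intervals.csv`` table (speaker, start_s, end_s)."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        spec_grp = h5.create_group("spec")
        for k, v in vars(session.spec).items():
            spec_grp.attrs[k] = v
        gt_grp = h5.create_group("ground_truth")
        gt_grp.create_dataset("kernels", data=session.gt.kernels)
        for k in ("gain_other", "gain_self", "crosstalk", "noise_sd", "seed"):
            gt_grp.attrs[k] = getattr(session.gt, k)
        for name, track in (("self", session.track_self), ("other", session.track_other)):
            g = h5.create_group(f"track_{name}")
            _write_intervals(g, "activity", track.activity)
            g.create_dataset("features", data=track.features)
        h5.create_dataset("eeg", data=session.eeg)
        h5.create_dataset("mic_self", data=session.mic_self)
        h5.create_dataset("mic_other", data=session.mic_other)
    write_intervals_csv(
        path.with_suffix(".intervals.csv"),
        {
            "self": session.track_self.activity,
            "other": session.track_other.activity,
        },
    )


def load_session(path) -> Session:
    with h5py.File(path, "r") as h5:
        spec = DialogueSpec(**{k: v.item() if hasattr(v, "item") else v for k, v in h5["spec"].attrs.items()})
        gt_grp = h5["ground_truth"]
        gt = GroundTruth(
            kernels=gt_grp["kernels"][()],
            **{k: float(gt_grp.attrs[k]) for k in ("gain_other", "gain_self", "crosstalk", "noise_sd")},
            seed=int(gt_grp.attrs["seed"]),
        )
        tracks = {}
        for name in ("self", "other"):
            g = h5[f"track_{name}"]
            tracks[name] = SpeechTrack(
                activity=[tuple(row) for row in g["activity"][()]],
                features=g["features"][()],
                fs_feature=spec.fs_feature,
            )
        return Session(
            spec=spec,
            gt=gt,
            track_self=tracks["self"],
            track_other=tracks["other"],
            eeg=h5["eeg"][()],
            mic_self=h5["mic_self"][()],
            mic_other=h5["mic_other"][()],
        )


def save_trf_h5(path, trf: np.ndarray, lag_ms: np.ndarray, band: str, condition: str, alphas=None) -> None:
    """mTRF tensor with labeled dims (channel, feature, lag in ms)."""
    with h5py.File(path, "a") as h5:
        name = f"trf/{band}/{condition or 'all'}"
        if name in h5:
            del h5[name]
        ds = h5.create_dataset(name, data=trf)
        ds.attrs["dims"] = "channel,feature,lag"
        ds.attrs["lag_ms"] = lag_ms
        if alphas is not None:
            ds.attrs["alphas"] = np.asarray(alphas)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))
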