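"""Lagged ridge encoding models (multivariate temporal response functions).

The model predicts each EEG channel at frame ``t`` from the preceding 600 ms
of stimulus features.  At 128 Hz, with the contemporaneous sample excluded
(the ~3 ms acoustic travel time from mouth to ear), this gives integer lags
1..77: 77 design columns per feature, 1232 for a 16-band spectrogram.  Ridge
weights, reshaped to (feature, lag), estimate the mTRF — the EEG impulse
response to the stimulus feature, read like an evoked potential.

Fitting follows the estimator/results idiom: build a :class:`SpeechEncoder`
from a feature stream, an EEG recording and a set of valid sample indices,
call :meth:`SpeechEncoder.fit` to run the contiguous (unshuffled) 5-fold
cross-validation with per-channel regularization chosen by inner 3-fold CV,
and read mTRFs, Pearson performance and the permutation-based significance
off the returned :class:`EncodingResults`.

The ridge solve uses centered normal equations through an eigendecomposition
of the Gram matrix.  This makes the sample-permutation null cheap: permuting
whole rows of the training design leaves X'X invariant, so each of the
thousands of surrogate refits costs one matrix-vector product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureSeries
from .preprocess import EEGRecording

__all__ = [
    "N_LAGS",
    "ALPHA_GRID",
    "LaggedDesignMatrix",
    "build_design_matrix",
    "fit_ridge",
    "select_alpha",
    "pearson_rows",
    "SpeechEncoder",
    "EncodingResults",
    "DegenerateDataError",
]

N_LAGS = 77  # 600 ms at 128 Hz minus the 3 ms (one-sample) discard
ALPHA_GRID = np.logspace(-2, 6, 13)


class DegenerateDataError(ValueError):
    """Correlation-based scoring is undefined (constant target)."""


@dataclass
class LaggedDesignMatrix:
    """Design matrix of lagged feature frames.

    Row i (for frame index t = sample_index[i]) holds features at frames
    t-1 .. t-n_lags, so column ``f * n_lags + (l-1)`` is feature f at lag l
    samples; no row uses frames at times > t.
    """

    X: np.ndarray
    n_lags: int
    n_features: int
    lag_ms: np.ndarray
    sample_index: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


def _as_feature_array(features) -> np.ndarray:
    if isinstance(features, FeatureSeries):
        return features.values
    return np.atleast_2d(np.asarray(features, dtype=float))


def build_design_matrix(
    features,
    sample_indices,
    n_lags: int = N_LAGS,
    fs: float = 128.0,
) -> LaggedDesignMatrix:
    """Assemble the lagged design matrix for the given sample indices.

    ``features`` is a FeatureSeries or (n_features, n_frames) array;
    ``sample_indices`` must all be >= n_lags so every lag exists.
    """
    vals = _as_feature_array(features)
    idx = np.asarray(sample_indices, dtype=int)
    if idx.size and (idx.min() < n_lags or idx.max() >= vals.shape[1]):
        raise IndexError("sample indices must lie in [n_lags, n_frames)")
    n_feat = vals.shape[0]
    cols = []
    for f in range(n_feat):
        # windows[j] = x[j : j+n_lags]; row for t is x[t-n_lags : t] reversed
        windows = np.lib.stride_tricks.sliding_window_view(vals[f], n_lags)
        cols.append(windows[idx - n_lags][:, ::-1])
    X = np.concatenate(cols, axis=1) if cols else np.empty((idx.size, 0))
    lag_ms = np.arange(1, n_lags + 1) / fs * 1000.0
    return LaggedDesignMatrix(
        X=np.ascontiguousarray(X),
        n_lags=n_lags,
        n_features=n_feat,
        lag_ms=lag_ms,
        sample_index=idx,
    )


def pearson_rows(pred: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between (k, n) arrays; NaN-safe to 0."""
    pred = np.atleast_2d(pred)
    obs = np.atleast_2d(obs)
    pc = pred - pred.mean(axis=1, keepdims=True)
    oc = obs - obs.mean(axis=1, keepdims=True)
    denom = np.sqrt((pc**2).sum(axis=1) * (oc**2).sum(axis=1))
    num = (pc * oc).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / denom
    return np.where(denom > 0, r, 0.0)


class _GramSolver:
    """Centered ridge solves sharing one eigendecomposition of X'X."""

    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        self.Xc = X - self.mean
        lam, V = np.linalg.eigh(self.Xc.T @ self.Xc)
        self.lam = np.maximum(lam, 0.0)
        self.V = V

    def solve(self, B: np.ndarray, alphas) -> np.ndarray:
        """Weights for centered cross-products B = Xc' yc, per column.

        ``alphas`` is a scalar or one value per column of B; returns (p, k).
        """
        B = np.atleast_2d(B.T).T  # ensure (p, k)
        alphas = np.broadcast_to(np.asarray(alphas, dtype=float), (B.shape[1],))
        Z = self.V.T @ B
        Z = Z / (self.lam[:, None] + alphas[None, :])
        return self.V @ Z

    def cross(self, Y: np.ndarray) -> np.ndarray:
        """Centered cross-products Xc' (Y - mean(Y)) for (n, k) targets."""
        Yc = Y - Y.mean(axis=0, keepdims=True)
        return self.Xc.T @ Yc


def fit_ridge(X: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """Ridge weights argmin ||y - Xw||^2 + alpha ||w||^2 (data centered).

    Returns the (p,) weight vector; the intercept is implicit in centering.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in ridge inputs")
    solver = _GramSolver(X)
    w = solver.solve(solver.cross(y[:, None]), alpha)
    return w[:, 0]


def _contiguous_folds(n: int, n_folds: int) -> list[np.ndarray]:
    if n < n_folds:
        raise ValueError(f"need at least {n_folds} samples, got {n}")
    return np.array_split(np.arange(n), n_folds)


def select_alpha(
    X: np.ndarray,
    y: np.ndarray,
    grid=ALPHA_GRID,
    n_inner: int = 3,
) -> float:
    """Grid value maximizing mean held-out Pearson r over inner contiguous CV."""
    alphas = _select_alphas_multi(np.asarray(X, float), np.asarray(y, float).reshape(-1, 1), grid, n_inner)
    return float(alphas[0])


def _select_alphas_multi(
    X: np.ndarray, Y: np.ndarray, grid, n_inner: int
) -> np.ndarray:
    """Per-column alpha by inner CV, sharing Gram factorizations."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("alpha grid must be non-empty and positive")
    if np.any(Y.std(axis=0) == 0):
        raise DegenerateDataError("constant target: correlation undefined")
    if grid.size == 1:
        return np.full(Y.shape[1], grid[0])
    n = X.shape[0]
    score = np.zeros((grid.size, Y.shape[1]))
    for val_idx in _contiguous_folds(n, n_inner):
        tr = np.setdiff1d(np.arange(n), val_idx, assume_unique=True)
        solver = _GramSolver(X[tr])
        B = solver.cross(Y[tr])
        Xv = X[val_idx] - solver.mean
        ym = Y[tr].mean(axis=0)
        for i, a in enumerate(grid):
            W = solver.solve(B, a)
            pred = Xv @ W + ym
            score[i] += pearson_rows(pred.T, Y[val_idx].T)
    # ties broken toward the smallest alpha (argmax returns first maximum)
    return grid[np.argmax(score, axis=0)]


# ---------------------------------------------------------------------------
# estimator / results
# ---------------------------------------------------------------------------


class SpeechEncoder:
    """Lagged ridge encoding model for one participant / band / condition.

    Parameters
    ----------
    features : FeatureSeries or (n_features, n_frames) array
        Stimulus features at the EEG frame rate.
    eeg : EEGRecording or (n_channels, n_frames) array
        EEG at the same rate.
    samples : array of int
        Valid sample indices (from ``extract_training_samples``).
    n_lags : int
        Lag window length in samples (default 77 = 600 ms minus one sample).
    n_folds : int
        Outer contiguous, unshuffled cross-validation folds (default 5).
    alpha_grid : array
        Candidate ridge strengths for inner 3-fold selection.
    """

    def __init__(
        self,
        features,
        eeg,
        samples,
        n_lags: int = N_LAGS,
        n_folds: int = 5,
        alpha_grid=ALPHA_GRID,
        n_inner: int = 3,
        fs: float = 128.0,
        band: str = "raw",
        condition: str = "",
    ):
        self.features = _as_feature_array(features)
        eeg_data = eeg.data if isinstance(eeg, EEGRecording) else np.atleast_2d(np.asarray(eeg, float))
        if isinstance(eeg, EEGRecording) and band == "raw":
            band = eeg.band
        if eeg_data.shape[1] != self.features.shape[1]:
            raise ValueError("features and EEG must share the frame axis")
        self.eeg = eeg_data
        samples = np.asarray(samples, dtype=int)
        # indices too early to carry a full lag window are excluded
        self.samples = samples[samples >= n_lags]
        self.n_lags = n_lags
        self.n_folds = n_folds
        self.alpha_grid = np.asarray(alpha_grid, dtype=float)
        self.n_inner = n_inner
        self.fs = fs
        self.band = band
        self.condition = condition
        self.design = build_design_matrix(self.features, self.samples, n_lags, fs)

    @classmethod
    def from_session(cls, session, mask, condition: str, perspective: str = "other", **kw):
        """Build from a simulated session and a ConditionMask.

        ``perspective='other'`` uses the partner's microphone features (E,
        E|B); ``'self'`` uses one's own (S, S|B).
        """
        from .segmentation import extract_training_samples

        base = condition.split("|")[-1] if "|" in condition else condition
        samples = extract_training_samples(mask, base, kw.pop("window_frames", N_LAGS))
        feats = session.mic_other if perspective == "other" else session.mic_self
        return cls(feats, session.eeg, samples, condition=condition, **kw)

    def fit(self) -> "EncodingResults":
        """Run the cross-validated fit and return the results object."""
        X = self.design.X
        Y = self.eeg[:, self.samples].T  # (n_samples, n_channels)
        n_ch = Y.shape[1]
        folds = _contiguous_folds(X.shape[0], self.n_folds)
        fold_w = np.zeros((self.n_folds, n_ch, X.shape[1]))
        alphas = np.zeros((self.n_folds, n_ch))
        r = np.zeros((self.n_folds, n_ch))
        caches = []
        for k, test in enumerate(folds):
            train = np.setdiff1d(np.arange(X.shape[0]), test, assume_unique=True)
            alphas[k] = _select_alphas_multi(X[train], Y[train], self.alpha_grid, self.n_inner)
            solver = _GramSolver(X[train])
            B = solver.cross(Y[train])
            W = solver.solve(B, alphas[k])  # (p, n_ch)
            fold_w[k] = W.T
            pred = (X[test] - solver.mean) @ W + Y[train].mean(axis=0)
            r[k] = pearson_rows(pred.T, Y[test].T)
            caches.append({"solver": solver, "train": train, "test": test})
        return EncodingResults(
            model=self,
            fold_weights=fold_w,
            alphas=alphas,
            r_folds=r,
            _fold_caches=caches,
        )


@dataclass
class EncodingResults:
    """Fold-resolved mTRFs, regularization and test-set performance."""

    model: SpeechEncoder
    fold_weights: np.ndarray  # (n_folds, n_channels, p)
    alphas: np.ndarray  # (n_folds, n_channels)
    r_folds: np.ndarray  # (n_folds, n_channels)
    _fold_caches: list = field(default_factory=list, repr=False)

    @property
    def n_channels(self) -> int:
        return self.fold_weights.shape[1]

    @property
    def trf(self) -> np.ndarray:
        """Fold-averaged mTRF, shape (n_channels, n_features, n_lags)."""
        d = self.model.design
        w = self.fold_weights.mean(axis=0)
        return w.reshape(self.n_channels, d.n_features, d.n_lags)

    @property
    def r(self) -> np.ndarray:
        """Fold-averaged Pearson correlation per channel."""
        return self.r_folds.mean(axis=0)

    @property
    def lag_ms(self) -> np.ndarray:
        return self.model.design.lag_ms

    def performance_frame(self, participant: str = "") -> pd.DataFrame:
        """Long-format (participant, band, condition, channel, fold, r, alpha)."""
        n_folds, n_ch = self.r_folds.shape
        fold, ch = np.meshgrid(np.arange(n_folds), np.arange(n_ch), indexing="ij")
        return pd.DataFrame(
            {
                "participant": participant,
                "band": self.model.band,
                "condition": self.model.condition,
                "channel": ch.ravel(),
                "fold": fold.ravel(),
                "r": self.r_folds.ravel(),
                "alpha": self.alphas.ravel(),
            }
        )

    def summary(self) -> str:
        """Plain-text per-channel summary table."""
        lines = [
            "Speech encoding model (lagged ridge mTRF)",
            f"  band={self.model.band or 'raw'} condition={self.model.condition or '-'} "
            f"n_samples={self.model.design.n_samples} "
            f"n_features={self.model.design.n_features} n_lags={self.model.design.n_lags} "
            f"folds={self.model.n_folds}",
            f"  mean r over channels: {self.r.mean():+.4f}",
            "  channel      r(mean)   r(sd folds)   median alpha",
        ]
        for c in range(self.n_channels):
            lines.append(
                f"  {c:7d}   {self.r[c]:+.4f}     {self.r_folds[:, c].std():.4f}"
                f"       {np.median(self.alphas[:, c]):.3g}"
            )
        return "\n".join(lines)

    def permutation_test(self, n_perm: int = 3000, seed=None) -> "PermutationTestResult":
        """Sample-permutation significance of the per-channel correlations.

        For every fold, whole rows of the training design are permuted
        ``n_perm`` times (lag structure within each row intact), the model is
        refitted with the originally selected alpha, and the original test
        set is predicted.  The p-value per channel and fold follows the
        add-one rule (N_exceed + 1) / (n_perm + 1) with strict exceedance.
        """
        from .permutation import PermutationTestResult  # local import, no cycle

        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        X = self.model.design.X
        Y = self.model.eeg[:, self.model.samples].T
        n_folds, n_ch = self.r_folds.shape
        exceed = np.zeros((n_folds, n_ch), dtype=int)
        null_r = np.zeros((n_folds, n_ch, n_perm))
        for k, cache in enumerate(self._fold_caches):
            solver, train, test = cache["solver"], cache["train"], cache["test"]
            Ytr = Y[train]
            ym = Ytr.mean(axis=0)
            Ytr_c = Ytr - ym
            Xv = X[test] - solver.mean
            Yt = Y[test].T
            for j in range(n_perm):
                perm = rng.permutation(train.size)
                B = solver.Xc.T @ Ytr_c[perm]
                W = solver.solve(B, self.alphas[k])
                pred = Xv @ W + ym
                null_r[k, :, j] = pearson_rows(pred.T, Yt)
            exceed[k] = (null_r[k] > self.r_folds[k][:, None]).sum(axis=1)
        p = (exceed + 1) / (n_perm + 1)
        return PermutationTestResult(
            rho_true=self.r_folds.copy(),
            rho_rand=null_r,
            n_perm=n_perm,
            n_exceed=exceed,
            p=p,
        )
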