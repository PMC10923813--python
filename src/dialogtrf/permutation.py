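"""Permutation null for encoding-model performance and significance rules.

The null distribution is built by shuffling whole samples (rows) of the
training design matrix — each row keeps its internal 600 ms lag structure —
refitting with the originally selected ridge strength, and predicting the
untouched evaluation set.  The p-value uses the add-one rule

    p = (N_exceed + 1) / (N_perm + 1)

with strict exceedance, so p is never 0 and lies on the achievable grid
[1/(N_perm+1), 1].  A channel is significant for a subject only when p falls
below the Bonferroni threshold (family alpha / n_channels) in *every* fold of
the unshuffled cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import _GramSolver, pearson_rows

__all__ = [
    "PermutationNull",
    "PermutationTestResult",
    "eq1_pvalue",
    "permutation_null_pvalue",
    "subject_significance_map",
]

N_PERM_DEFAULT = 3000


def eq1_pvalue(n_exceed, n_perm):
    """Add-one permutation p-value; never 0 by construction."""
    n_exceed = np.asarray(n_exceed)
    if np.any(n_exceed < 0) or np.any(n_exceed > n_perm):
        raise ValueError("n_exceed must lie in [0, n_perm]")
    return (n_exceed + 1) / (n_perm + 1)


@dataclass
class PermutationNull:
    """Null correlations and the permutation p-value for one channel/fold."""

    rho_rand: np.ndarray
    rho_true: float
    n_perm: int
    n_exceed: int
    p: float


@dataclass
class PermutationTestResult:
    """Fold x channel permutation test attached to an EncodingResults."""

    rho_true: np.ndarray  # (n_folds, n_channels)
    rho_rand: np.ndarray  # (n_folds, n_channels, n_perm)
    n_perm: int
    n_exceed: np.ndarray  # (n_folds, n_channels)
    p: np.ndarray  # (n_folds, n_channels)

    def significant_channels(self, alpha_fw: float = 0.05, n_channels: int | None = None) -> np.ndarray:
        """Boolean per channel: p below alpha_fw/n_channels in all folds."""
        m = self.p.shape[1] if n_channels is None else n_channels
        return np.all(self.p < alpha_fw / m, axis=0)

    def to_frame(self) -> pd.DataFrame:
        n_folds, n_ch = self.p.shape
        fold, ch = np.meshgrid(np.arange(n_folds), np.arange(n_ch), indexing="ij")
        return pd.DataFrame(
            {
                "channel": ch.ravel(),
                "fold": fold.ravel(),
                "rho_true": self.rho_true.ravel(),
                "p": self.p.ravel(),
            }
        )


def permutation_null_pvalue(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    alpha: float,
    n_perm: int = N_PERM_DEFAULT,
    seed=None,
) -> PermutationNull:
    """Permutation null for a single channel on a fixed train/test split.

    The ridge strength is held at the original model's ``alpha``; only the
    rows of the training design are permuted, and predictions always use the
    original test-set features.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    X_train = np.asarray(X_train, float)
    y_train = np.asarray(y_train, float).ravel()
    solver = _GramSolver(X_train)
    ym = y_train.mean()
    yc = y_train - ym
    Xv = np.asarray(X_test, float) - solver.mean
    w = solver.solve(solver.Xc.T @ yc[:, None], alpha)
    rho_true = float(pearson_rows((Xv @ w)[:, 0] + ym, y_test)[0])
    null = np.empty(n_perm)
    for j in range(n_perm):
        # permuting rows of X with y fixed == permuting y against fixed X:
        # the Gram matrix and column means are invariant either way
        perm = rng.permutation(y_train.size)
        wj = solver.solve(solver.Xc.T @ yc[perm, None], alpha)
        null[j] = pearson_rows((Xv @ wj)[:, 0] + ym, y_test)[0]
    n_exceed = int((null > rho_true).sum())
    return PermutationNull(
        rho_rand=null,
        rho_true=rho_true,
        n_perm=n_perm,
        n_exceed=n_exceed,
        p=float(eq1_pvalue(n_exceed, n_perm)),
    )


def subject_significance_map(
    pvals_per_subject,
    alpha_fw: float = 0.05,
    n_channels: int = 128,
) -> np.ndarray:
    """Per-channel count of subjects significant in all folds.

    ``pvals_per_subject`` is an iterable of (n_folds, n_channels) arrays of
    p-values in (0, 1].  A subject counts for a channel iff
    p < alpha_fw / n_channels in every fold.
    """
    counts = None
    for p in pvals_per_subject:
        p = np.asarray(p)
        if np.any(p <= 0) or np.any(p > 1):
            raise ValueError("p-values must lie in (0, 1]")
        sig = np.all(p < alpha_fw / n_channels, axis=0).astype(int)
        counts = sig if counts is None else counts + sig
    if counts is None:
        raise ValueError("no subjects provided")
    return counts
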