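"""Group-level comparisons of encoding performance across dialog conditions.

Per-channel paired comparisons between conditions (e.g. listening to
external vs self-produced speech) use the exact two-sided Wilcoxon
signed-rank test, with a Bonferroni threshold of family-alpha / n_channels;
effect sizes are paired Cohen's d (mean of differences over their sample SD)
and JZS paired-t Bayes factors on the log10 scale, binned into the customary
evidence labels.  Cluster-level inference over the (feature x lag) mTRF
plane uses threshold-free cluster enhancement scored against a sign-flip
permutation distribution of its maximum.  Benjamini-Hochberg FDR adjustment
is provided as an alternative to Bonferroni.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ChannelComparison",
    "wilcoxon_map",
    "lateralization_test",
    "tfce_one_sample",
    "effect_stats",
    "evidence_label",
    "fdr_bh",
    "bonferroni_threshold",
]

N_CHANNELS_FULL = 128


def bonferroni_threshold(alpha_fw: float = 0.05, n_channels: int = N_CHANNELS_FULL) -> float:
    return alpha_fw / n_channels


@dataclass
class ChannelComparison:
    """Per-channel paired comparison between two conditions (A vs B)."""

    p_uncorrected: np.ndarray
    d_prime: np.ndarray
    log10_bf10: np.ndarray
    n: int
    bonferroni: float

    @property
    def log10_bf01(self) -> np.ndarray:
        return -self.log10_bf10

    @property
    def significant(self) -> np.ndarray:
        return self.p_uncorrected < self.bonferroni

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": np.arange(self.p_uncorrected.size),
                "p_uncorrected": self.p_uncorrected,
                "p_fdr": fdr_bh(self.p_uncorrected),
                "d_prime": self.d_prime,
                "log10_bf10": self.log10_bf10,
                "significant_bonferroni": self.significant,
            }
        )


def _exact_wilcoxon_p(diff: np.ndarray) -> float:
    """Two-sided signed-rank p, exact (enumerative) for n <= 25."""
    method = "exact" if diff.size <= 25 else "approx"
    return float(stats.wilcoxon(diff, alternative="two-sided", method=method).pvalue)


def effect_stats(rA, rB) -> tuple[float, float, str]:
    """Paired Cohen's d, log10 JZS Bayes factor, and its evidence label.

    d = mean(diff) / SD(diff) with the sample SD (ddof=1); the Bayes factor
    is the paired-t JZS with Cauchy prior scale sqrt(2)/2.
    """
    diff = np.asarray(rA, float) - np.asarray(rB, float)
    sd = diff.std(ddof=1)
    d = float(diff.mean() / sd) if sd > 0 else 0.0
    n = diff.size
    if sd > 0:
        t = diff.mean() / (sd / np.sqrt(n))
        bf10 = float(pg.bayesfactor_ttest(t, n, paired=True, r=np.sqrt(2) / 2))
        log10_bf10 = float(np.log10(bf10))
    else:
        log10_bf10 = 0.0
    return d, log10_bf10, evidence_label(log10_bf10)


def evidence_label(log10_bf: float) -> str:
    """Evidence bins on the log10 Bayes-factor scale."""
    if log10_bf > 2:
        return "decisive"
    if log10_bf > 0.5:
        return "substantial"
    if log10_bf > 0:
        return "positive"
    return "none"


def wilcoxon_map(
    rA: np.ndarray,
    rB: np.ndarray,
    alpha_fw: float = 0.05,
    n_channels_correction: int | None = None,
) -> ChannelComparison:
    """Exact signed-rank Wilcoxon per channel on paired (subject, channel) r.

    Arrays are (n_subjects, n_channels); the Bonferroni threshold attached to
    the result divides ``alpha_fw`` by the number of channels tested (or an
    explicit ``n_channels_correction``, e.g. 128 on the full montage).
    """
    rA = np.atleast_2d(np.asarray(rA, float))
    rB = np.atleast_2d(np.asarray(rB, float))
    if rA.shape != rB.shape:
        raise ValueError("paired arrays must have equal shape")
    n, n_ch = rA.shape
    if n < 5:
        raise ValueError("need at least 5 paired samples")
    p = np.empty(n_ch)
    d = np.empty(n_ch)
    bf = np.empty(n_ch)
    for c in range(n_ch):
        diff = rA[:, c] - rB[:, c]
        if np.all(diff == 0):
            raise ValueError(f"degenerate test: all-zero differences on channel {c}")
        p[c] = _exact_wilcoxon_p(diff)
        d[c], bf[c], _ = effect_stats(rA[:, c], rB[:, c])
    m = n_ch if n_channels_correction is None else n_channels_correction
    return ChannelComparison(
        p_uncorrected=p, d_prime=d, log10_bf10=bf, n=n, bonferroni=alpha_fw / m
    )


def lateralization_test(
    r: np.ndarray,
    channel_names: list[str],
    left: list[str],
    right: list[str],
) -> ChannelComparison:
    """Left-vs-right hemispheric comparison of per-channel correlations.

    Each hemisphere contributes its selected frontal channels (12 in the full
    montage); values are sorted within hemisphere and paired by rank (the
    montages differ, so there is no anatomical 1:1 pairing), then compared
    with the exact signed-rank test.  Identical hemispheres are degenerate:
    p is reported as 1 with a warning.
    """
    if set(left) & set(right):
        raise ValueError("left and right channel sets must be disjoint")
    if len(left) != len(right):
        raise ValueError("hemisphere channel sets must have equal size")
    r = np.asarray(r, float)
    idx = {name: i for i, name in enumerate(channel_names)}
    lvals = np.sort(r[[idx[c] for c in left]])[::-1]
    rvals = np.sort(r[[idx[c] for c in right]])[::-1]
    diff = lvals - rvals
    n = diff.size
    if np.all(diff == 0):
        warnings.warn("identical hemispheric values: degenerate test, p reported as 1")
        p = 1.0
        d, bf = 0.0, 0.0
    else:
        p = _exact_wilcoxon_p(diff)
        d, bf, _ = effect_stats(lvals, rvals)
    return ChannelComparison(
        p_uncorrected=np.array([p]),
        d_prime=np.array([d]),
        log10_bf10=np.array([bf]),
        n=n,
        bonferroni=0.05,
    )


def tfce_one_sample(
    trf_stack: np.ndarray,
    n_perm: int = 4096,
    start: float = 0.0,
    step: float = 0.2,
    seed=None,
    e_power: float = 0.5,
    h_power: float = 2.0,
) -> np.ndarray:
    """One-sample sign-flip TFCE over a (subjects, features, lags) stack.

    Returns the p-map (features, lags), scored against the permutation
    distribution of the maximum TFCE statistic; lattice adjacency over the
    feature x lag plane; ``n_perm`` is capped at the 2^N exhaustive bound.
    """
    from mne.stats import permutation_cluster_1samp_test

    X = np.asarray(trf_stack, float)
    if X.ndim != 3 or X.shape[0] < 2:
        raise ValueError("need (n_subjects >= 2, n_features, n_lags)")
    shape = X.shape[1:]
    if not np.any(X):
        return np.ones(shape)
    n_perm = int(min(n_perm, 2 ** X.shape[0]))
    threshold = dict(start=start, step=step, e_power=e_power, h_power=h_power)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_obs, clusters, cluster_pv, _ = permutation_cluster_1samp_test(
            X,
            threshold=threshold,
            n_permutations=n_perm,
            tail=0,
            adjacency=None,
            rng=np.random.default_rng(seed),
            out_type="mask",
            verbose=False,
        )
    pmap = np.ones(shape)
    for cl, p in zip(clusters, cluster_pv):
        pmap[cl] = np.minimum(pmap[cl], p)
    return pmap


def fdr_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvals = np.asarray(pvals, float)
    if np.any(pvals <= 0) or np.any(pvals > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]
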