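"""Histogram mutual-information estimation on equiprobable bins.

Both the auto- and cross-mutual-information markers reduce to the same
primitive: discretize each signal into ``n_bins`` marginally equiprobable
bins (rank-based, so the estimate is invariant under any monotone amplitude
rescaling), count joint occupancy, and evaluate the plug-in estimator

    I(X; Y) = sum_ij p_ij * log( p_ij / (p_i q_j) )   [nats]

Ties are assigned average ranks, so a constant signal collapses into a
single bin and its mutual information is exactly 0.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def equiprobable_bins(x: np.ndarray, n_bins: int = 16) -> np.ndarray:
    """Rank-based discretization into ``n_bins`` near-equiprobable bins."""
    x = np.asarray(x, dtype=float)
    n = x.size
    ranks = rankdata(x, method="average")  # ties share a bin
    return np.clip(((ranks - 0.5) * n_bins / n).astype(int), 0, n_bins - 1)


def joint_counts(bx: np.ndarray, by: np.ndarray, n_bins: int = 16) -> np.ndarray:
    """Joint occupancy counts of two pre-binned sequences, shape (n_bins, n_bins)."""
    return np.bincount(bx * n_bins + by, minlength=n_bins * n_bins).reshape(
        n_bins, n_bins
    )


def entropy_from_counts(counts: np.ndarray) -> float:
    """Plug-in Shannon entropy (nats) of a count vector/table."""
    counts = np.asarray(counts, dtype=float).ravel()
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def mutual_information_from_counts(counts: np.ndarray) -> float:
    """Plug-in mutual information (nats) from a joint count table.

    Always >= 0 up to floating rounding; exactly symmetric under transpose.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        return 0.0
    pxy = counts / total
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    mask = pxy > 0
    ratio = pxy[mask] / np.outer(px, py)[mask]
    return max(float((pxy[mask] * np.log(ratio)).sum()), 0.0)


def binned_mutual_information(
    x: np.ndarray, y: np.ndarray, n_bins: int = 16
) -> float:
    """Mutual information (nats) between two signals via equiprobable bins."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0  # degenerate marginal
    bx = equiprobable_bins(x, n_bins)
    by = equiprobable_bins(y, n_bins)
    return mutual_information_from_counts(joint_counts(bx, by, n_bins))


def lagged_auto_information(
    x: np.ndarray, lags: range, n_bins: int = 16
) -> np.ndarray:
    """I(x_t; x_{t+tau}) for each lag, binning the full series once."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return np.zeros(len(lags))
    bx = equiprobable_bins(x, n_bins)
    out = np.empty(len(lags))
    for k, tau in enumerate(lags):
        if tau >= x.size:
            out[k] = 0.0
            continue
        out[k] = mutual_information_from_counts(
            joint_counts(bx[:-tau], bx[tau:], n_bins)
        )
    return out
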