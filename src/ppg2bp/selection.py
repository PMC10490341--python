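"""RReliefF feature scoring and negative-score elimination.

The regression Relief estimator scores each feature by how much its
differences co-occur with target differences among nearest neighbors: for
every anchor instance the k nearest neighbors (Manhattan distance) contribute
rank-decayed probabilities of "different target" (N_dC), "different feature"
(N_dF) and their conjunction (N_dC&dF); the weight of feature f is

    W[f] = N_dC&dF[f] / N_dC  -  (N_dF[f] - N_dC&dF[f]) / (m - N_dC)

with target and feature differences range-scaled to [0, 1].  Features with
negative scores are eliminated; zero scores are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, SelectionError


@dataclass
class FeatureScores:
    """Per-feature RReliefF weights for one phase/target combination."""

    weights: np.ndarray
    feature_names: list[str] | None = None
    target: str | None = None
    phase: str | None = None
    k_neighbors: int = 10
    sigma_decay: float = 50.0


def _rank_weights(k: int, sigma: float) -> np.ndarray:
    """Distance-rank weights d ~ exp(-(rank/sigma)^2), normalized over k."""
    r = np.arange(1, k + 1)
    w = np.exp(-((r / sigma) ** 2))
    return w / w.sum()


def rrelieff(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    sigma: float = 50.0,
    n_anchors: int | None = None,
    seed: int | None = None,
    feature_names: list[str] | None = None,
    target: str | None = None,
    phase: str | None = None,
) -> FeatureScores:
    """RReliefF weights for a continuous target.

    All instances serve as anchors in deterministic order by default;
    ``n_anchors`` with ``seed`` samples a random subset.  Requires
    n >= k + 1 and no missing values.  A constant target yields all-zero
    weights with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, f = X.shape
    if np.isnan(X).any() or np.isnan(y).any():
        raise DomainError("RReliefF input must not contain missing values")
    if n <= k:
        raise DomainError(f"need n > k neighbors (n={n}, k={k})")
    y_range = np.ptp(y)
    if y_range == 0:
        warnings.warn("constant target: all RReliefF weights are 0", stacklevel=2)
        return FeatureScores(np.zeros(f), feature_names, target, phase, k, sigma)
    x_range = np.ptp(X, axis=0)
    safe_range = np.where(x_range == 0, 1.0, x_range)

    if n_anchors is not None and n_anchors < n:
        rng = np.random.default_rng(seed)
        anchors = np.sort(rng.choice(n, size=n_anchors, replace=False))
    else:
        anchors = np.arange(n)
    m = len(anchors)
    rw = _rank_weights(k, sigma)

    n_dc = 0.0
    n_df = np.zeros(f)
    n_dcdf = np.zeros(f)
    for i in anchors:
        dist = np.abs(X - X[i]).sum(axis=1)
        dist[i] = np.inf
        order = np.argsort(dist, kind="stable")[:k]
        dy = np.abs(y[order] - y[i]) / y_range
        dx = np.abs(X[order] - X[i]) / safe_range  # (k, f)
        n_dc += rw @ dy
        n_df += rw @ dx
        n_dcdf += (rw * dy) @ dx
    if n_dc == 0 or n_dc >= m:
        warnings.warn("degenerate target-difference mass; weights set to 0",
                      stacklevel=2)
        return FeatureScores(np.zeros(f), feature_names, target, phase, k, sigma)
    w = n_dcdf / n_dc - (n_df - n_dcdf) / (m - n_dc)
    return FeatureScores(w, feature_names, target, phase, k, sigma)


def select_nonnegative(scores: FeatureScores) -> np.ndarray:
    """Boolean mask keeping features with weight >= 0 (zero kept).

    Raises SelectionError when every score is negative.
    """
    w = np.asarray(scores.weights, dtype=float)
    if not np.all(np.isfinite(w)):
        raise SelectionError("non-finite feature scores")
    mask = w >= 0
    if not mask.any():
        raise SelectionError("all feature scores negative: degenerate selection")
    return mask
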