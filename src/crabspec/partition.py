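"""SPXY sample partitioning (Kennard-Stone on a joint X-Y distance).

Pairwise Euclidean distances in spectrum space (X) and response space (Y)
are each normalized by their maximum and summed; training samples are then
picked greedily: start from the most distant pair, and repeatedly add the
sample whose minimum joint distance to the already-selected set is
largest (maximin).  Categorical origin labels enter the Y distance by
one-hot encoding (0 within class, sqrt(2) across classes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["PartitionResult", "spxy_split", "joint_distance_matrix"]


@dataclass(frozen=True)
class PartitionResult:
    """Disjoint train/test index sets covering 0..n_total-1."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        train = np.asarray(self.train_idx, dtype=int)
        test = np.asarray(self.test_idx, dtype=int)
        object.__setattr__(self, "train_idx", train)
        object.__setattr__(self, "test_idx", test)
        union = np.union1d(train, test)
        if np.intersect1d(train, test).size:
            raise ValueError("train and test indices overlap")
        if union.size != self.n_total or (union != np.arange(self.n_total)).any():
            raise ValueError("train and test indices must partition 0..n_total-1")


def _encode_y(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim == 1 and not np.issubdtype(y.dtype, np.number):
        classes, codes = np.unique(y, return_inverse=True)
        onehot = np.zeros((y.size, classes.size))
        onehot[np.arange(y.size), codes] = 1.0
        return onehot
    return np.atleast_2d(np.asarray(y, dtype=float).reshape(len(y), -1))


def joint_distance_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sum of max-normalized Euclidean distance matrices in X and Y."""
    X = np.asarray(X, dtype=float)
    dx = squareform(pdist(X))
    max_dx = dx.max()
    if max_dx == 0.0:
        raise ValueError("all spectra are identical: SPXY X-distance degenerate")
    dy = squareform(pdist(_encode_y(y)))
    max_dy = dy.max()
    d = dx / max_dx
    if max_dy > 0.0:
        d = d + dy / max_dy
    return d


def spxy_split(X: np.ndarray, y: np.ndarray, n_train: int) -> PartitionResult:
    """Deterministic SPXY train/test split.

    Ties are broken toward the lowest index so the split is reproducible.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= n_train <= n:
        raise ValueError(f"n_train must be in [2, {n}], got {n_train}")
    d = joint_distance_matrix(X, y)

    # seed pair: maximal joint distance, lexicographically first on ties
    iu = np.triu_indices(n, k=1)
    flat = d[iu]
    best = np.argmax(flat)  # argmax returns the first (lowest (i,j)) maximum
    selected = [int(iu[0][best]), int(iu[1][best])]
    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False

    min_dist = np.minimum(d[selected[0]], d[selected[1]])
    while len(selected) < n_train:
        candidates = np.nonzero(remaining)[0]
        pick = candidates[np.argmax(min_dist[candidates])]
        selected.append(int(pick))
        remaining[pick] = False
        min_dist = np.minimum(min_dist, d[pick])

    train = np.sort(np.asarray(selected, dtype=int))
    test = np.nonzero(remaining)[0]
    return PartitionResult(train_idx=train, test_idx=test, n_total=n)
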