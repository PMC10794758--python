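"""Class-imbalance handling: random undersampling and SMOTE.

Real lncRNA/mRNA collections are strongly imbalanced (sometimes 40:1).  Two
remedies are offered: (1) undersample — keep every minority row and a
seeded uniform subset of majority rows of equal size; (2) SMOTE — grow the
minority class by interpolating between a minority point and one of its k
nearest minority neighbours, x + u*(z - x) with u ~ Uniform(0, 1), until
the classes are equal.  Balancing is meant for TRAINING data only; the
evaluation split must stay untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BalancedSet:
    """Balanced (X, y) with provenance: which rows are synthetic."""

    X: np.ndarray
    y: np.ndarray
    method: str
    seed: int
    synthetic: np.ndarray  # boolean mask over rows
    source_index: np.ndarray  # original row index, -1 for synthetic rows

    @property
    def n_synthetic(self) -> int:
        return int(self.synthetic.sum())


def _class_split(y: np.ndarray) -> tuple[int, int]:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    if counts[0] == counts[1]:
        minority, majority = classes[0], classes[1]
    return int(minority), int(majority)


def undersample(X: np.ndarray, y: np.ndarray, seed: int) -> BalancedSet:
    """Keep all minority rows and an equal-size seeded random subset of
    majority rows; shuffle the result deterministically."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    minority, majority = _class_split(y)
    rng = np.random.default_rng(seed)
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y == majority)
    chosen_maj = rng.choice(maj_idx, size=len(min_idx), replace=False)
    keep = np.concatenate([min_idx, chosen_maj])
    keep = rng.permutation(keep)
    return BalancedSet(
        X=X[keep],
        y=y[keep],
        method="undersample",
        seed=seed,
        synthetic=np.zeros(len(keep), dtype=bool),
        source_index=keep,
    )


def smote(X: np.ndarray, y: np.ndarray, k_neighbors: int = 5, seed: int = 0) -> BalancedSet:
    """Oversample the minority class by segment interpolation until equal.

    Each synthetic point picks a minority row x uniformly at random and one
    of its k nearest minority neighbours z (Euclidean, effective
    k = min(k_neighbors, minority_size - 1)), then emits x + u*(z - x).
    Existing rows are never modified.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    minority, majority = _class_split(y)
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y == majority)
    if len(min_idx) < 2:
        raise ValueError("SMOTE needs at least 2 minority rows (no line segments exist)")
    n_needed = len(maj_idx) - len(min_idx)
    rng = np.random.default_rng(seed)
    xm = X[min_idx]
    k_eff = min(k_neighbors, len(min_idx) - 1)
    # brute-force neighbour table; minority classes here are small
    d2 = np.sum((xm[:, None, :] - xm[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    neighbour_idx = np.argsort(d2, axis=1, kind="stable")[:, :k_eff]
    synth = np.empty((n_needed, X.shape[1]))
    for i in range(n_needed):
        a = rng.integers(len(min_idx))
        z = neighbour_idx[a, rng.integers(k_eff)]
        u = rng.random()
        synth[i] = xm[a] + u * (xm[z] - xm[a])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    synthetic = np.zeros(len(y_out), dtype=bool)
    synthetic[len(y):] = True
    source_index = np.concatenate([np.arange(len(y)), np.full(n_needed, -1)])
    return BalancedSet(
        X=X_out,
        y=y_out,
        method="smote",
        seed=seed,
        synthetic=synthetic,
        source_index=source_index,
    )


def balance(X: np.ndarray, y: np.ndarray, method: str, seed: int, k_neighbors: int = 5) -> BalancedSet:
    """Dispatch to :func:`undersample`, :func:`smote`, or pass through."""
    if method == "undersample":
        return undersample(X, y, seed)
    if method == "smote":
        return smote(X, y, k_neighbors=k_neighbors, seed=seed)
    if method == "none":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        return BalancedSet(
            X=X, y=y, method="none", seed=seed,
            synthetic=np.zeros(len(y), dtype=bool),
            source_index=np.arange(len(y)),
        )
    raise ValueError(f"unknown balance method {method!r}")
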