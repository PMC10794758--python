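"""PCA-reduced k-mer composition features (DC: dinucleotide, TC: trinucleotide).

Overlapping k-mer frequencies give a 16-dimensional (k=2) or 64-dimensional
(k=3) composition vector per sequence; PCA on the training matrix reduces
each family to (by default) 15 principal components.  Frequencies rather
than raw counts enter PCA so that sequence length does not confound the
composition signal.

The PCA here is a deliberately small, deterministic implementation (SVD of
the centred matrix, components sign-fixed so the loading of largest absolute
value is positive) so that runs are bit-reproducible; it is cross-checked
against an independent eigendecomposition in the test suite.  Models fit on
training rows only; held-out rows are transformed with the frozen model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .physchem import all_kmers, kmer_frequencies

logger = logging.getLogger(__name__)

DEFAULT_N_COMPONENTS = 15


def composition_vector(seq: str, k: int) -> np.ndarray:
    """4^k vector of overlapping k-mer frequencies (N-free windows), sum 1."""
    freqs = kmer_frequencies(seq, k)
    order = all_kmers(k)
    return np.array([freqs.get(m, 0.0) for m in order])


def composition_matrix(records, k: int) -> pd.DataFrame:
    """Rows = records, columns = the 4^k k-mers, values = frequencies."""
    order = all_kmers(k)
    rows = []
    for rec in records:
        try:
            rows.append(composition_vector(rec.seq, k))
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
    return pd.DataFrame(rows, index=[r.id for r in records], columns=order)


@dataclass(frozen=True)
class PCAModel:
    """Frozen mean + orthonormal components + explained-variance ratios."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, dim), rows orthonormal
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            mean=np.asarray(d["mean"]),
            components=np.asarray(d["components"]),
            explained_variance=np.asarray(d["explained_variance"]),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"]),
        )


def fit_pca(matrix: np.ndarray | pd.DataFrame, n_components: int) -> PCAModel:
    """Mean-centred PCA via SVD, components sorted by decreasing variance.

    Requesting components beyond the matrix rank is allowed: the surplus
    components carry zero explained variance (a warning is logged).
    """
    x = np.asarray(matrix, dtype=float)
    n, dim = x.shape
    if n < n_components:
        raise ValueError(f"need at least {n_components} rows, got {n}")
    if n_components > dim:
        raise ValueError(f"n_components={n_components} exceeds dimension {dim}")
    mean = x.mean(axis=0)
    centred = x - mean
    _, svals, vt = np.linalg.svd(centred, full_matrices=True)
    variances = np.zeros(dim)
    variances[: len(svals)] = svals**2 / (n - 1)
    total = variances.sum()
    components = vt[:n_components].copy()
    # sign convention: largest-|loading| entry of each component is positive
    for row in components:
        pivot = np.argmax(np.abs(row))
        if row[pivot] < 0:
            row *= -1
    ev = variances[:n_components]
    rank = int(np.sum(svals > svals[0] * max(n, dim) * np.finfo(float).eps)) if len(svals) else 0
    if n_components > rank:
        logger.warning(
            "requested %d components but data rank is %d; surplus components "
            "have zero explained variance",
            n_components,
            rank,
        )
    ratio = ev / total if total > 0 else np.zeros_like(ev)
    return PCAModel(
        mean=mean,
        components=components,
        explained_variance=ev,
        explained_variance_ratio=ratio,
    )


def transform(model: PCAModel, matrix: np.ndarray | pd.DataFrame, prefix: str = "pc") -> pd.DataFrame:
    """Project rows onto the model's components: scores = (X - mean) @ V^T."""
    x = np.asarray(matrix, dtype=float)
    if x.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"dimension mismatch: data has {x.shape[1]} columns, "
            f"model expects {model.mean.shape[0]}"
        )
    scores = (x - model.mean) @ model.components.T
    index = matrix.index if isinstance(matrix, pd.DataFrame) else None
    cols = [f"{prefix}{j + 1}" for j in range(model.n_components)]
    return pd.DataFrame(scores, index=index, columns=cols)


def fit_transform_composition(
    train_records,
    k: int,
    n_components: int = DEFAULT_N_COMPONENTS,
    prefix: str = "pc",
    min_retained: float = 0.95,
) -> tuple[PCAModel, pd.DataFrame]:
    """Fit PCA on training composition vectors and return the scores.

    Logs a warning when the retained variance falls below ``min_retained``
    (the expectation that ~95% of composition variability survives the
    reduction), without asserting it: arbitrary data may legitimately
    violate it.
    """
    comp = composition_matrix(train_records, k)
    model = fit_pca(comp.values, n_components)
    retained = float(model.explained_variance_ratio.sum())
    if retained < min_retained:
        logger.warning(
            "PCA(k=%d, %d comps) retains %.1f%% variance, below %.0f%%",
            k, n_components, 100 * retained, 100 * min_retained,
        )
    scores = transform(model, comp, prefix=prefix)
    return model, scores
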