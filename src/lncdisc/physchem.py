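"""Physicochemical energy features (DP, TP): solvation, stacking, H-bonding.

Each k-mer (dinucleotide, k=2, or trinucleotide, k=3) carries a triple of
energies in kcal/mol, supplied as a TSV table.  The experimental lineage of
such tables is MD simulation of tetranucleotides, with lower orders obtained
by averaging over every position at which the shorter k-mer occurs inside a
longer one; :func:`derive_lower_order_table` reproduces that averaging for
any table.  A sequence's three features are the k-mer-frequency-weighted
mean energies — empirical overlapping k-mer frequencies by default, or the
stationary distribution of the sequence's first-order k-mer Markov chain via
``weighting="stationary"``.

Tables are DNA-alphabet keyed; RNA sequences are handled upstream by the
U->T normalisation at load time.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENERGY_COLUMNS = ["solvation", "stacking", "hbond"]
_DATA_DIR = Path(__file__).parent / "data"


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


@dataclass(frozen=True)
class EnergyTable:
    """Complete map from the 4^k k-mers to (solvation, stacking, hbond)."""

    k: int
    entries: dict[str, tuple[float, float, float]] = field(repr=False)

    def __post_init__(self) -> None:
        expected = set(all_kmers(self.k))
        got = set(self.entries)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ValueError(
                f"energy table for k={self.k}: missing {missing[:8]}, "
                f"unexpected {extra[:8]}"
            )
        for m, triple in self.entries.items():
            if any(not np.isfinite(v) for v in triple):
                raise ValueError(f"non-finite energy for k-mer {m}")

    def energies(self, kmer: str) -> tuple[float, float, float]:
        return self.entries[kmer]

    def as_frame(self) -> pd.DataFrame:
        idx = all_kmers(self.k)
        return pd.DataFrame(
            [self.entries[m] for m in idx], index=idx, columns=ENERGY_COLUMNS
        )


@dataclass(frozen=True)
class TransitionMatrix:
    """First-order transition structure over overlapping k-mer states.

    ``counts[i, j]`` is the number of adjacent N-free k-mer pairs
    (state i followed by state j); ``probs`` is the row-normalised matrix,
    all-zero on rows whose k-mer never occurs with a successor.  Only
    transitions between k-mers overlapping in k-1 bases can be nonzero,
    giving the 16x16 (k=2) and 64x64 (k=3) pair structures.
    """

    k: int
    states: tuple[str, ...]
    counts: np.ndarray
    probs: np.ndarray


def load_energy_table(path: str | Path, k: int) -> EnergyTable:
    """Load a TSV with columns kmer/solvation/stacking/hbond; keys case-insensitive."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"kmer": str})
    required = {"kmer", *ENERGY_COLUMNS}
    if not required.issubset(df.columns):
        raise ValueError(f"energy table must have columns {sorted(required)}")
    entries: dict[str, tuple[float, float, float]] = {}
    for _, row in df.iterrows():
        key = str(row["kmer"]).upper()
        if key in entries:
            raise ValueError(f"duplicate k-mer {key} in {path}")
        try:
            triple = tuple(float(row[c]) for c in ENERGY_COLUMNS)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric energy for k-mer {key}") from exc
        entries[key] = triple
    return EnergyTable(k=k, entries=entries)


def example_energy_table(k: int) -> EnergyTable:
    """The bundled illustrative (synthetic) energy table for k in {2, 3}.

    These values are generated, not measured; they exist so the pipeline is
    runnable and testable without the user's own table.  Supply a real table
    for scientific use.
    """
    if k not in (2, 3):
        raise ValueError("bundled example tables cover k=2 and k=3 only")
    name = {2: "example_dinucleotide_energies.tsv", 3: "example_trinucleotide_energies.tsv"}[k]
    return load_energy_table(_DATA_DIR / name, k)


def derive_lower_order_table(table: EnergyTable) -> EnergyTable:
    """Average an order-k table down to order k-1.

    The energy of each (k-1)-mer m is the unweighted arithmetic mean over
    all occurrences of m as a contiguous substring of an order-k k-mer: each
    containing k-mer contributes once per distinct occurrence position, so
    e.g. AAA contributes twice to AA.
    """
    if table.k < 3:
        raise ValueError("cannot derive below k=2")
    km1 = table.k - 1
    sums: dict[str, np.ndarray] = {m: np.zeros(3) for m in all_kmers(km1)}
    counts: dict[str, int] = {m: 0 for m in sums}
    for big in all_kmers(table.k):
        e = np.asarray(table.entries[big])
        for pos in range(table.k - km1 + 1):
            sub = big[pos : pos + km1]
            sums[sub] += e
            counts[sub] += 1
    entries = {m: tuple(sums[m] / counts[m]) for m in sums}
    return EnergyTable(k=km1, entries=entries)


def _valid_kmer_positions(seq: str, k: int) -> tuple[list[str], np.ndarray]:
    """All overlapping k-mers of seq with a validity (N-free) mask."""
    kmers = [seq[i : i + k] for i in range(len(seq) - k + 1)]
    valid = np.array(["N" not in m for m in kmers])
    return kmers, valid


def transition_matrix(seq: str, k: int) -> TransitionMatrix:
    """Count adjacent overlapping k-mer pairs and row-normalise."""
    if len(seq) < k + 1:
        raise ValueError(f"sequence shorter than k+1={k + 1}")
    states = tuple(all_kmers(k))
    index = {m: i for i, m in enumerate(states)}
    counts = np.zeros((len(states), len(states)), dtype=np.int64)
    kmers, valid = _valid_kmer_positions(seq, k)
    for t in range(len(kmers) - 1):
        if valid[t] and valid[t + 1]:
            counts[index[kmers[t]], index[kmers[t + 1]]] += 1
    if counts.sum() == 0:
        raise ValueError("no valid (N-free) k-mer transitions in sequence")
    row_sums = counts.sum(axis=1, keepdims=True)
    probs = np.divide(
        counts, row_sums, out=np.zeros_like(counts, dtype=float), where=row_sums > 0
    )
    return TransitionMatrix(k=k, states=states, counts=counts, probs=probs)


def kmer_frequencies(seq: str, k: int) -> dict[str, float]:
    """Overlapping k-mer frequencies over N-free k-mers, summing to 1."""
    kmers, valid = _valid_kmer_positions(seq, k)
    total = int(valid.sum())
    if total == 0:
        raise ValueError(f"no N-free {k}-mer in sequence")
    freqs: dict[str, float] = {}
    for m, ok in zip(kmers, valid):
        if ok:
            freqs[m] = freqs.get(m, 0.0) + 1.0
    return {m: c / total for m, c in freqs.items()}


def stationary_distribution(tm: TransitionMatrix, tol: float = 1e-12, max_iter: int = 10_000) -> dict[str, float]:
    """Stationary distribution of the k-mer chain by power iteration,
    restricted to the states that actually occur."""
    occupied = np.flatnonzero(tm.counts.sum(axis=1) + tm.counts.sum(axis=0) > 0)
    p = tm.probs[np.ix_(occupied, occupied)]
    # renormalise rows (absorbing last k-mer may have had no successor)
    rs = p.sum(axis=1, keepdims=True)
    p = np.divide(p, rs, out=np.full_like(p, 1.0 / len(occupied)), where=rs > 0)
    pi = np.full(len(occupied), 1.0 / len(occupied))
    for _ in range(max_iter):
        nxt = pi @ p
        if np.abs(nxt - pi).max() < tol:
            pi = nxt
            break
        pi = nxt
    pi = pi / pi.sum()
    return {tm.states[s]: float(pi[i]) for i, s in enumerate(occupied)}


def energy_features(
    seq: str,
    table: EnergyTable,
    weighting: str = "empirical",
) -> tuple[float, float, float]:
    """Weighted-mean (solvation, stacking, hbond) energies of a sequence.

    Weights are the empirical overlapping k-mer frequencies, or with
    ``weighting="stationary"`` the stationary distribution of the fitted
    first-order k-mer transition matrix.
    """
    if weighting == "empirical":
        weights = kmer_frequencies(seq, table.k)
    elif weighting == "stationary":
        weights = stationary_distribution(transition_matrix(seq, table.k))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    out = np.zeros(3)
    for m, w in weights.items():
        out += w * np.asarray(table.entries[m])
    return tuple(float(v) for v in out)


def energy_feature_frame(records, table: EnergyTable, prefix: str, weighting: str = "empirical") -> pd.DataFrame:
    """Per-record energy features, columns ``{prefix}_{solvation,stacking,hbond}``."""
    rows = []
    for rec in records:
        try:
            rows.append((rec.id, *energy_features(rec.seq, table, weighting)))
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
    cols = ["id"] + [f"{prefix}_{c}" for c in ENERGY_COLUMNS]
    return pd.DataFrame(rows, columns=cols).set_index("id")
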