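"""Seeded generator of labelled synthetic transcript sequences.

The classifier exploits one structural asymmetry of real transcriptomes:
coding sequence is a concatenation of codons drawn from a biased usage
distribution (hence a period-3 signal and skewed k-mer composition), while
long non-coding sequence has no reading frame and is well described at
short range by a low-order Markov chain.  The generator emulates exactly
that: the mRNA-like class draws codons i.i.d. from a 64-codon usage
simplex sharpened by a temperature-like bias strength; the lncRNA-like
class runs a first-order nucleotide Markov chain started from its
stationary distribution.

With ``codon_bias_strength = 0`` the coding class collapses to i.i.d.
uniform nucleotides, matching the default (uniform-chain) non-coding class
— the built-in negative control.  No ORF grammar, splicing or sequencing
noise is simulated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .seqio import LABEL_LNCRNA, LABEL_MRNA, SeqRecord

CODONS = tuple("".join(p) for p in itertools.product("ACGT", repeat=3))
NUCS = "ACGT"


def default_codon_usage(seed: int, n_favoured: int = 20, favoured_mass: float = 0.9) -> np.ndarray:
    """A skewed 64-codon usage: ~90% of mass on a seeded random 20-codon
    subset (Dirichlet weights), the rest spread over the remaining codons.

    Emulates codon bias without copying any organism's usage table.
    """
    rng = np.random.default_rng(seed)
    usage = np.empty(64)
    favoured = rng.choice(64, size=n_favoured, replace=False)
    rest = np.setdiff1d(np.arange(64), favoured)
    usage[favoured] = rng.dirichlet(np.ones(n_favoured)) * favoured_mass
    usage[rest] = rng.dirichlet(np.ones(len(rest))) * (1 - favoured_mass)
    return usage / usage.sum()


def uniform_markov() -> np.ndarray:
    return np.full((4, 4), 0.25)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one simulated two-class dataset."""

    n_per_class: int = 500
    length_range: tuple[int, int] = (200, 600)
    codon_usage: np.ndarray | None = None  # None -> default_codon_usage(seed)
    markov_order1: np.ndarray = field(default_factory=uniform_markov)
    codon_bias_strength: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        lo, hi = self.length_range
        if lo < 9 or hi < lo:
            raise ValueError("length_range must satisfy 9 <= min <= max")
        if self.codon_bias_strength < 0:
            raise ValueError("codon_bias_strength must be >= 0")
        m = np.asarray(self.markov_order1)
        if m.shape != (4, 4) or np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0):
            raise ValueError("markov_order1 must be a 4x4 row-stochastic matrix")
        if self.codon_usage is not None:
            u = np.asarray(self.codon_usage)
            if u.shape != (64,) or np.any(u < 0) or not np.isclose(u.sum(), 1.0):
                raise ValueError("codon_usage must be a 64-simplex vector")

    def effective_codon_usage(self) -> np.ndarray:
        """Base usage sharpened by the bias strength: p_i ∝ u_i^t.

        t = 0 gives the uniform 64-codon distribution (i.i.d. uniform
        nucleotides); larger t concentrates mass on the favoured codons.
        """
        u = (
            np.asarray(self.codon_usage, dtype=float)
            if self.codon_usage is not None
            else default_codon_usage(self.seed)
        )
        if self.codon_bias_strength == 0:
            return np.full(64, 1 / 64)
        p = np.where(u > 0, u, 1e-300) ** self.codon_bias_strength
        return p / p.sum()


def _draw_lengths(rng: np.random.Generator, config: GeneratorConfig, n: int) -> np.ndarray:
    lo, hi = config.length_range
    return rng.integers(lo, hi + 1, size=n)


def generate_mrna_like(config: GeneratorConfig) -> list[SeqRecord]:
    """Codon-concatenation sequences with the configured usage bias.

    Each length is drawn uniformly from the range then rounded down to a
    codon multiple (resampled if that leaves zero codons).
    """
    rng = np.random.default_rng(config.seed)
    usage = config.effective_codon_usage()
    records = []
    for i in range(config.n_per_class):
        n_codons = 0
        while n_codons == 0:
            n_codons = int(_draw_lengths(rng, config, 1)[0]) // 3
        idx = rng.choice(64, size=n_codons, p=usage)
        seq = "".join(CODONS[j] for j in idx)
        records.append(SeqRecord(id=f"mrna_{i:05d}", seq=seq, label=LABEL_MRNA))
    return records


def markov_stationary(m: np.ndarray, tol: float = 1e-13, max_iter: int = 100_000) -> np.ndarray:
    """Stationary distribution of a 4x4 row-stochastic chain by power iteration."""
    pi = np.full(4, 0.25)
    for _ in range(max_iter):
        nxt = pi @ m
        if np.abs(nxt - pi).max() < tol:
            return nxt / nxt.sum()
        pi = nxt
    raise ValueError("Markov chain has no reachable stationary distribution")


def generate_lncrna_like(config: GeneratorConfig) -> list[SeqRecord]:
    """First-order Markov sequences with no frame structure."""
    rng = np.random.default_rng(config.seed + 1)
    m = np.asarray(config.markov_order1, dtype=float)
    pi = markov_stationary(m)
    records = []
    for i in range(config.n_per_class):
        length = int(_draw_lengths(rng, config, 1)[0])
        states = np.empty(length, dtype=np.int64)
        u = rng.random(length)
        cum = np.cumsum(m, axis=1)
        states[0] = int(np.searchsorted(np.cumsum(pi), u[0], side="right"))
        prev = states[0]
        for t in range(1, length):
            prev = int(np.searchsorted(cum[prev], u[t], side="right"))
            states[t] = prev
        seq = "".join(NUCS[min(s, 3)] for s in states)
        records.append(SeqRecord(id=f"lnc_{i:05d}", seq=seq, label=LABEL_LNCRNA))
    return records


def generate_dataset(config: GeneratorConfig) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """(lncRNA-like, mRNA-like) record lists, n_per_class each."""
    return generate_lncrna_like(config), generate_mrna_like(config)
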