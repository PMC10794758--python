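"""Reading, validating and labelling transcript sequences.

Sequences arrive as FASTA, one file per class (lncRNA vs mRNA); the class
label is a property of the file, never parsed from headers.  On load,
sequences are normalised to the DNA alphabet: uppercased, U mapped to T and
IUPAC ambiguity codes other than N collapsed to N.  Downstream feature code
treats N positions as missing (they contribute to no indicator vector and no
k-mer count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

logger = logging.getLogger(__name__)

LABEL_LNCRNA = 0
LABEL_MRNA = 1

# IUPAC nucleotide codes beyond A/C/G/T/U/N; all map to N on load.
_AMBIGUITY = set("RYSWKMBDHV")
_VALID = set("ACGTUN") | _AMBIGUITY


class FastaParseError(ValueError):
    """Malformed FASTA input (e.g. sequence data before the first header)."""


@dataclass(frozen=True)
class SeqRecord:
    """One labelled transcript sequence.

    ``label`` is 0 for lncRNA, 1 for mRNA, or None when unlabelled.
    """

    id: str
    seq: str
    label: int | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.seq != self.seq.upper():
            raise ValueError(f"record {self.id!r}: sequence must be uppercase")

    @property
    def length(self) -> int:
        return len(self.seq)


def normalize_sequence(raw: str, *, record_id: str = "?") -> str:
    """Uppercase, map U->T, collapse ambiguity codes to N; reject junk."""
    seq = raw.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(
            f"record {record_id!r}: invalid characters {sorted(bad)!r}"
        )
    n_ambig = sum(seq.count(c) for c in _AMBIGUITY)
    if n_ambig:
        logger.warning(
            "record %r: %d ambiguity code(s) mapped to N", record_id, n_ambig
        )
        seq = "".join("N" if c in _AMBIGUITY else c for c in seq)
    return seq.replace("U", "T")


def read_fasta(path: str | Path, label: int | None = None) -> list[SeqRecord]:
    """Read one FASTA file into normalised, uniformly labelled records.

    Records preserve file order.  Empty entries are skipped with a warning;
    sequence data before the first ``>`` header raises :class:`FastaParseError`
    with the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_headers_first(path)
    records: list[SeqRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        raw = str(entry.seq)
        if not raw:
            logger.warning("skipping empty FASTA entry %r", entry.id)
            continue
        records.append(
            SeqRecord(id=entry.id, seq=normalize_sequence(raw, record_id=entry.id), label=label)
        )
    return records


def _check_headers_first(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                return
            raise FastaParseError(
                f"{path}:{lineno}: sequence data before first FASTA header"
            )


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    bio = [BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def filter_by_length(
    records: list[SeqRecord],
    min_len: int = 200,
    max_n_frac: float = 0.1,
) -> list[SeqRecord]:
    """Keep records with length >= ``min_len`` and N fraction <= ``max_n_frac``.

    The 200 nt default is the conventional lncRNA length floor.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if not 0.0 <= max_n_frac <= 1.0:
        raise ValueError("max_n_frac must be in [0, 1]")
    kept = [
        r
        for r in records
        if r.length >= min_len and r.seq.count("N") / r.length <= max_n_frac
    ]
    removed = len(records) - len(kept)
    if removed:
        logger.info("filter_by_length removed %d of %d records", removed, len(records))
    return kept
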