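import numpy as np
import pytest

from lncdisc import physchem, seqio


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_entry_fasta(tmp_path):
    path = tmp_path / "two.fasta"
    path.write_text(">seq1 first\nACGTACGT\nACGT\n>seq2\nacgu\n")
    return path


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture
def random_records(rng):
    return [
        seqio.SeqRecord(id=f"r{i}", seq=random_seq(rng, int(rng.integers(60, 200))), label=i % 2)
        for i in range(12)
    ]


def toy_table(k, values=None, seed=0):
    """A fully specified random (or constant) energy table for tests."""
    kmers = physchem.all_kmers(k)
    if values is not None:
        entries = {m: (values, values, values) for m in kmers}
    else:
        r = np.random.default_rng(seed)
        entries = {m: tuple(r.normal(-10, 3, 3)) for m in kmers}
    return physchem.EnergyTable(k=k, entries=entries)
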