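"""lncdisc: discriminating lncRNA from mRNA transcript sequences.

Feature families: base periodicity (period-3 power-spectrum peak and SNR),
di-/trinucleotide physicochemical energies (solvation, stacking, hydrogen
bonding) and PCA-reduced k-mer composition; 16 named feature combinations;
class balancing by undersampling or SMOTE; a small BCE-trained neural
classifier; classification metrics and MLE distribution fitting; and a
seeded synthetic-sequence generator for end-to-end testing.
"""

from . import (
    balance,
    combos,
    composition,
    evalstats,
    mlp,
    periodicity,
    physchem,
    pipeline,
    seqio,
    synthetic,
)

__version__ = "0.1.0"

__all__ = [
    "balance",
    "combos",
    "composition",
    "evalstats",
    "mlp",
    "periodicity",
    "physchem",
    "pipeline",
    "seqio",
    "synthetic",
    "__version__",
]
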