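"""Period-3 power spectrum of a coding-like vs a random sequence.

A perfect codon repeat puts all non-DC spectral power into the N/3 bin; a
random sequence has a flat spectrum and SNR near 1.
"""

import numpy as np

from lncdisc import periodicity

coding_like = "ATG" * 100  # 300 nt of perfect codon structure
rng = np.random.default_rng(0)
random_seq = "".join(rng.choice(list("ACGT"), size=300))

for name, seq in [("codon repeat", coding_like), ("random", random_seq)]:
    ps = periodicity.power_spectrum(seq)
    print(f"{name:>12}: peak S[{ps.peak_index}] = {ps.peak:10.1f}   SNR = {ps.snr:7.2f}")

print()
print("The codon repeat concentrates power 3*(N/3)^2 = 30000 in the period-3")
print("bin (SNR far above the mRNA/lncRNA working threshold of ~4); the")
print("random sequence's SNR ~ 1 means its period-3 power is indistinguishable")
print("from the average spectral bin.")
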