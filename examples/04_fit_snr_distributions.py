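"""MLE distribution fitting of per-sequence SNR values with AIC selection.

Fits lognormal, gamma and exponential families to the SNR of the coding-like
class and prints the AIC table; the minimal-AIC family is the selected model.
"""

import numpy as np

from lncdisc import evalstats, periodicity, synthetic

cfg = synthetic.GeneratorConfig(
    n_per_class=400, length_range=(200, 600), codon_bias_strength=2.0, seed=3
)
mrna = synthetic.generate_mrna_like(cfg)
snr = np.array([periodicity.power_spectrum(r.seq).snr for r in mrna])
snr = snr[snr > 0]

best, fits = evalstats.select_best_fit(snr)
print(f"SNR of {len(snr)} coding-like sequences (mean {snr.mean():.2f}):\n")
print(f"{'family':>12} {'params':>42} {'loglik':>12} {'AIC':>12}")
for fit in fits.values():
    params = ", ".join(f"{k}={v:.4f}" for k, v in fit.params.items())
    marker = "  <- selected" if fit.family == best else ""
    print(f"{fit.family:>12} {params:>42} {fit.loglik:12.2f} {fit.aic:12.2f}{marker}")

print()
print("Lower AIC = better fit after penalising parameters; positively skewed")
print("SNR values are typically captured by a two-parameter skewed family.")
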