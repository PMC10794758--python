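"""Train the classifier on synthetic data: periodicity alone vs a combined combo.

Simulates 300 sequences per class (codon bias strength 2), trains the BP
(periodicity-only) and BPDCTC (periodicity + composition) combinations, and
prints the six held-out metrics for each.
"""

from lncdisc import pipeline, synthetic

cfg = synthetic.GeneratorConfig(
    n_per_class=300, length_range=(200, 600), codon_bias_strength=2.0, seed=11
)
lnc, mrna = synthetic.generate_dataset(cfg)
records = lnc + mrna

for combo, balance in [("BP", "none"), ("BPDCTC", "smote")]:
    res = pipeline.train_evaluate(records, combo, balance_method=balance, seed=11)
    m = res.metrics
    print(f"combo {combo:7s} (balance={balance}):")
    print(f"  accuracy {m.accuracy:.4f}  precision {m.precision:.4f}  "
          f"recall {m.recall:.4f}")
    print(f"  ROC-AUC  {m.roc_auc:.4f}  PRC-AUC   {m.prc_auc:.4f}  "
          f"F1     {m.f1:.4f}")

print()
print("Positive class is mRNA. BP alone separates the classes because codon")
print("bias creates a period-3 peak; adding composition PCs tightens accuracy.")
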