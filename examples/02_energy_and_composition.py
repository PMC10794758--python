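"""Physicochemical energy features and PCA-reduced composition of a small sample.

Uses the bundled ILLUSTRATIVE energy tables (synthetic values); supply your
own TSV for real analyses.
"""

from lncdisc import composition, physchem, synthetic

cfg = synthetic.GeneratorConfig(n_per_class=50, length_range=(200, 400), seed=7)
lnc, mrna = synthetic.generate_dataset(cfg)
records = lnc + mrna

table2 = physchem.example_energy_table(2)
solv, stack, hbond = physchem.energy_features(records[0].seq, table2)
print(f"first sequence ({records[0].id}) dinucleotide energies [kcal/mol]:")
print(f"  solvation {solv:8.3f}   stacking {stack:8.3f}   H-bond {hbond:8.3f}")
print("  (frequency-weighted means over the sequence's overlapping dimers)")

model, scores = composition.fit_transform_composition(records, k=3, n_components=15)
retained = model.explained_variance_ratio.sum()
print(f"\ntrinucleotide composition PCA: 64 dims -> 15 PCs, "
      f"{100 * retained:.1f}% variance retained")
print("first 3 PC scores of the first two sequences:")
print(scores.iloc[:2, :3].round(4).to_string())
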