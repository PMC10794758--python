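# lncdisc

Discriminating long non-coding RNA (lncRNA) from messenger RNA (mRNA)
transcript sequences using three sequence-intrinsic feature families, a
small neural classifier, and honest class-imbalance handling.

Annotating transcripts as coding vs non-coding is a recurring step in
genome annotation. `lncdisc` is for bioinformaticians who want a compact,
fully inspectable pipeline: every feature has a closed-form definition,
every stochastic step is seeded, and the whole workflow is testable without
any external download thanks to a built-in synthetic-sequence generator.

## The features and the model

Three families of per-sequence features:

- **Base periodicity (BP, 2 features).** For each base *b* ∈ {A,C,G,T} the
  binary indicator vector *u_b* marks its positions; the power spectrum is
  S[k] = Σ_b |Σ_n u_b[n]·e^(−2πikn/N)|². Codon structure gives coding
  sequence a peak at k ≈ N/3. The features are the peak S[round(N/3)] and
  its SNR = peak / mean(S[1..N−1]). Parseval's identity
  Σ_k S[k] = N·(#non-N positions) holds exactly (no zero-padding).
- **Physicochemical energies (DP/TP, 3 features each).** Solvation,
  stacking and hydrogen-bonding energies per dinucleotide (DP) or
  trinucleotide (TP), from a user-supplied TSV table; the per-sequence
  feature is the k-mer-frequency-weighted mean energy Σ_m f(m)·E(m).
  Lower-order tables can be derived from higher-order ones by positional
  averaging. A clearly marked *synthetic illustrative* table is bundled.
- **k-mer composition (DC/TC, 15 PCs each).** Overlapping di-/trinucleotide
  frequencies (16- and 64-dimensional), reduced by PCA fit on training
  rows only, with a deterministic sign convention.

Sixteen named combinations of these families (BP, DP, TP, DC, TC, DPTP,
BPDP, … DPTPDCTC, each up to 15 columns) feed a single-hidden-layer MLP
with a sigmoid output, trained by seeded mini-batch gradient descent on the
binary cross-entropy Loss(y, ŷ) = −y·log ŷ − (1−y)·log(1−ŷ). Class
imbalance is removed on the training split only, by random undersampling
or SMOTE. Reported metrics: accuracy, precision, recall, ROC-AUC, PRC-AUC
(average precision) and F1, with mRNA as the positive class; per-sequence
SNR/peak statistics can additionally be fit by lognormal/gamma/exponential
MLE with AIC model selection.

## Worked example

```bash
python examples/03_train_classifier.py
```

simulates 300 sequences per class (coding-like: biased codon concatenation;
non-coding-like: first-order Markov chain), trains two combinations and
prints:

```
combo BP      (balance=none):
  accuracy 1.0000  precision 1.0000  recall 1.0000
  ROC-AUC  1.0000  PRC-AUC   1.0000  F1     1.0000
combo BPDCTC  (balance=smote):
  accuracy 1.0000  precision 1.0000  recall 1.0000
  ROC-AUC  1.0000  PRC-AUC   1.0000  F1     1.0000
```

At codon-bias strength 2 the synthetic classes are essentially perfectly
separable — the period-3 SNR of the coding-like class (mean ≈ 60) sits far
above the non-coding background (≈ 1), so held-out metrics saturate at 1.0.
The interesting control is the other direction: with bias 0 and matched
composition the same pipeline scores ROC-AUC ≈ 0.5 (chance), confirming the
classifier learns the structural signal and nothing else. The other
examples (`examples/01…04`) walk through the spectrum, the energy/PCA
features and the distribution fitting individually.

The same workflow is available from the shell:

```bash
lncdisc simulate --n-per-class 300 --seed 11 --out-dir sim
lncdisc train sim/lncrna.fasta sim/mrna.fasta --combo BPDCTC --balance smote --seed 11
lncdisc combos          # list the 16 feature combinations
```

Every run writes a `manifest.json` (command line, seed, settings, input
checksums) sufficient to reproduce it exactly.

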