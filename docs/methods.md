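# Methods

## Spectral base-periodicity features

Each sequence of length N yields four binary indicator vectors, one per
base; positions holding N (or any ambiguity code, collapsed to N at load)
are zero in all four, so an ambiguous position contributes no power. The
power spectrum is the sum over bases of squared DFT magnitudes. Choices:

- **DFT length = N, no zero-padding.** Keeps Parseval exact
  (Σ_k S[k] = N · #non-N positions, enforced at tolerance 1e−9 in tests)
  and keeps the period-3 frequency at the bin round(N/3).
- **Peak index = round(N/3)** when N is not a multiple of 3: the nearest
  DFT bin to the 1/3 frequency.
- **SNR = S[round(N/3)] / mean(S[1..N−1])**, the classical period-3
  signal-to-noise definition. The DC bin is excluded because it encodes
  base composition, not periodicity. The mean runs over all N−1 non-DC
  bins rather than the first half; by conjugate symmetry of real signals
  the two conventions give identical values up to bookkeeping of the
  Nyquist bin, and the full range needs no parity case-split. A
  homopolymer has zero power in every non-DC bin; its SNR is defined as 0.
- Minimum length 9 nt, so the peak bin is ≥ 3 and distinct from DC.

Useful exact anchors: (ATG)×m has S[N/3] = 3m² (each of the three present
bases contributes DFT magnitude m at the period-3 bin), and i.i.d. uniform sequences have flat
expected spectra, hence mean SNR ≈ 1 — both are asserted in the tests.

## Physicochemical energy features

Energy tables map each k-mer (k = 2 or 3) to (solvation, stacking,
hydrogen-bonding) energies in kcal/mol. Tables are user-supplied TSVs; the
bundled `example_*_energies.tsv` files are **synthetic illustrative
values** (generated with a GC-content trend plus seeded noise) so the
pipeline runs without a real table — they carry no experimental meaning.
RNA is handled in its DNA alphabet (U→T at load), matching how such tables
are parameterised.

`derive_lower_order_table` averages an order-k table down to order k−1:
each (k−1)-mer's energy is the unweighted arithmetic mean over every
occurrence position inside every containing k-mer (so AAA contributes
twice to AA). Position-unweighted averaging was chosen over
genome-frequency weighting because it is table-intrinsic; the alternative
would require an external occurrence prior.

The per-sequence features are weighted mean energies Σ_m f(m)·E(m). The
default weights f are the empirical overlapping k-mer frequencies over
N-free windows (a probability distribution by construction). A
`weighting="stationary"` switch instead uses the stationary distribution
of the sequence's first-order k-mer transition matrix (power iteration,
tolerance 1e−12, restricted to occupied states); for long sequences the
two coincide up to end effects, and the empirical default remains
well-defined on short sequences. The 16×16 / 64×64 transition matrices
(row-stochastic on occupied rows) are exposed in their own right.

## Composition PCA

Overlapping k-mer **frequencies** (not counts) form the 16-/64-dimensional
composition vectors: transcript lengths span two orders of magnitude, and
raw counts would make length the dominant axis. PCA is a small in-house
implementation — SVD of the centred training matrix — because determinism
matters here: components are sorted by decreasing variance and sign-fixed
so each component's largest-magnitude loading is positive, making runs
bit-reproducible across platforms. It is verified against a covariance
eigendecomposition oracle and scikit-learn in the tests. Defaults: 15
components per family, fit on the pooled two-class **training** rows only
(held-out rows are transformed with the frozen model; a sentinel test
asserts the fit cannot see them). Retained variance below 95% is logged as
a warning, never asserted — arbitrary data may violate it (the uniform-ish
synthetic sequences retain ~92%).

## The 16 combinations

The registry fixes the published count arithmetic: DP=3, TP=3, DPTP=3+3,
DC=15, TC=15, BP=2, BPDP=2+3, BPTP=2+3, BPDPTP=2+3+3, BPDC=2+13,
BPTC=2+13, BPDCTC=2+7+6, DPDC=3+12, TPTC=3+12, DCTC=8+7, DPTPDCTC=3+4+3+5.
Where a combination takes fewer than 15 DC/TC columns, the **top-variance**
PCs are kept — the canonical choice, since no finer selection rule is
recoverable. DP/TP truncation keeps (solvation, stacking, hbond) order.
Assembly checks row-id alignment across families and records per-column
provenance.

## Balancing

`undersample` keeps all minority rows plus a seeded uniform
without-replacement subset of majority rows; `smote` interpolates
x + u·(z − x) between a random minority row and one of its
k = min(5, minority−1) nearest minority neighbours (Euclidean,
brute-force neighbour table — minority classes here are small). SMOTE runs
in the assembled feature space so neighbourhoods are taken in the
geometry the model sees, and only ever on the training split. k = 5 is
the canonical SMOTE default. SMOTE's known tendency to overfit is not
mitigated beyond reporting both balancing approaches side by side
(`pipeline.paired_balance_report`).

## Classifier

A numpy MLP: inputs z-scored with training statistics (the BP peak spans
orders of magnitude against the energy features; unscaled training would
be dominated by it), one hidden layer of width max(8, 2·input_dim)
(input dims range 2–15, so a width-scaled single layer covers the regime;
depth/width are configurable), ReLU default, sigmoid output, mean BCE with
probabilities clipped to [1e−12, 1−1e−12], plain mini-batch gradient
descent (lr 0.01, 200 epochs, batch 32 — all exposed). Initialisation is
seeded He-style; training is bit-deterministic given the seed. Analytic
gradients are verified against central finite differences (relative 1e−5)
on a 2-4-1 network. Evaluation protocol: seeded stratified 80/20 split.

## Metrics and distribution fitting

Positive class = mRNA (label 1) everywhere. ROC-AUC is trapezoidal
integration over all thresholds and is tested to equal the O(n²)
Mann-Whitney probability to 1e−10 (ties = ½). PRC-AUC is average precision
with step interpolation, avoiding the optimistic linear interpolation of a
trapezoid in PR space. Precision with no positive predictions is recorded
as 0 with a flag.

MLE fits for positive samples: exponential rate = 1/mean and lognormal
(μ = mean of logs, σ² = 1/n-variance of logs) in closed form; the gamma
shape solves log a − ψ(a) = log(mean) − mean(log) by Newton iteration
(tolerance 1e−10, ≤ 200 iterations, halving on negative steps, the usual
(3−s+√((s−3)²+24s))/(12s) start). Constant samples are rejected as
degenerate (σ = 0 / diverging shape) rather than crashed on. Model
selection is by AIC = 2k − 2·loglik, ties toward fewer parameters; AIC was
chosen over raw likelihood or visual inspection as the standard penalised
criterion. Zero SNR values (homopolymers) are excluded from fitting with a
logged count, since all three families have positive support.

## Synthetic generator

Study conditions used throughout the tests and the acceptance script: 500
sequences per class, lengths uniform on 200–600 nt (200 = the lncRNA
definition floor; 600 keeps the suite fast while leaving ≥ 66 codons of
signal), codon bias strength 2, seed threaded from the caller.

- **Coding-like class:** i.i.d. codons from a 64-codon usage simplex;
  the default usage puts ~90% of mass on a seeded random 20-codon subset
  (Dirichlet weights) — emulating the magnitude of real codon bias without
  copying any organism's table — and is sharpened as p ∝ u^t by the bias
  strength t. Lengths are rounded down to codon multiples. t = 0 recovers
  i.i.d. uniform nucleotides exactly.
- **Non-coding-like class:** a first-order nucleotide Markov chain started
  from its stationary distribution; default transition matrix uniform, so
  the two classes are composition-matched at t = 0 (the negative control:
  end-to-end ROC-AUC ≈ 0.5).

What the generator does **not** emulate: ORF/stop-codon grammar, splicing
and isoforms, GC heterogeneity between real lncRNA and mRNA, length-class
correlation, sequencing error, and the heavy-tailed SNR distributions of
real transcripts. Consequently, passing tests demonstrate that the
pipeline detects the structural signal it claims to detect — they do not
certify real-data accuracy, and on the synthetic SNR samples the
AIC-selected family is typically gamma rather than the lognormal reported
for real transcriptomes. Labels come from which generator (or which input
FASTA file) produced a sequence, never from header parsing.

## Degenerate inputs and numerical conventions

Sequences shorter than 9 nt, all-N sequences, single-class label vectors,
singleton minority classes and non-positive samples for distribution
fitting all raise informative errors naming the offending record where
applicable. Seeds derived from a user seed stay below 2³¹. CLI exit codes:
0 success, 2 input error, 3 numeric failure; logs go to stderr, data to
files, and every run writes a manifest (command, seed, settings, input
checksums) sufficient to reproduce it.

## Known limitations

- The energy features are only as meaningful as the supplied table; the
  bundled one is synthetic.
- The stationary-weighting option assumes the sequence's k-mer chain is
  effectively irreducible on its occupied states.
- No cross-validation — a single stratified split — and no hyperparameter
  search; the classifier is intentionally minimal.
- PRC/ROC estimates on small held-out splits (n = 200) carry sampling
  error of a few percent.
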