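# Methods

## Dose-range labeling

LD50 (mg/kg body weight) is the dose lethal to half the test animals;
toxicity is inversely related to it. The binary scheme marks a record
toxic (label 1) when `ld50 < cutoff` and nontoxic otherwise; the value
exactly at the cutoff is nontoxic. That boundary convention is a
declared choice, made so that the binary scheme at 500 mg/kg coarsens
the four-category scheme exactly: categories use the half-open
intervals `[0,50) < [50,500) < [500,1000) < [1000,∞)` ordered from most
to least toxic, and merging the lower two against the upper two
reproduces `label_binary(·, 500)` bit-exactly. Cutoffs of 250, 500, 750
and 1000 mg/kg nest monotonically: lowering the cutoff can only shrink
the toxic set.

Route-of-exposure strings are normalized to lowercase through a small
synonym table (`po`/`per os`/`gavage` → `oral`, `intraperitoneal` →
`ip`, …). Unrecognized values are kept verbatim and only match a filter
that names them; records pass unfiltered queries regardless.

## SMILES one-hot codec

Tokenization is strictly per character — two-letter element symbols
(`Cl`, `Br`) intentionally split into two tokens — and case-sensitive
(aromatic `c` ≠ aliphatic `C`). A dictionary assigns indices 1..M by
descending corpus frequency with ties broken by first occurrence; an
explicit mapping can be supplied when a fixed published ordering must
be reproduced. A string of length ℓ ≤ L becomes an `L × M` binary
matrix with one set bit per occupied row and all-zero padding rows
after row ℓ; the padding symbol is *not* part of the alphabet, so M
counts only real characters. Decoding validates the
one-hot-then-padding layout and rejects rows with ≠1 set bits or
occupied rows after padding. Out-of-vocabulary characters always raise;
they are never silently mapped to padding, because a silently truncated
molecule would yield a confidently wrong prediction. L is fixed at the
training-corpus maximum and persisted with the model; longer inference
strings are reported per row rather than crashing a batch.

The tokenizer dictionary and L are built over the full corpus before
splitting (alphabet discovery is not a fitted statistic); imputation
medians and standardization statistics, by contrast, are fitted on
training rows only.

## The hybrid network

Implemented from scratch in NumPy (float64, CPU): valid-mode 1-D
convolution, ReLU, non-overlapping max pooling, dense layers, inverted
dropout, sigmoid/softmax heads with the matched cross-entropy gradient,
and Adam. Backpropagation is verified against central finite
differences in the test suite. Architecture defaults: two convolution
blocks (64 then 128 filters, kernel length 4, pool length 2), hidden
widths (256, 128), dropout 0.25, learning rate 1e-3, batch size 32, at
most 100 epochs with early stopping on validation AUC (patience 10, 10%
internal validation split when none is supplied, best weights
restored). The merge happens after each branch's last layer: branch
outputs are concatenated and a single dense head classifies — the
simplest reading of "merge then classify" when the exact junction is
open. The optional fingerprint branch treats the MACCS bit vector as a
length-166 single-channel sequence under the same convolution stack; it
is off by default since most experiments use descriptors + SMILES only.
Weight init is He-normal (Glorot would also serve; ReLU stacks favour
He). One seed drives initialization, shuffling, dropout and the
internal validation split, so a fit is bit-reproducible
single-threaded; non-finite loss aborts with diagnostics rather than
silently producing NaN probabilities.

Hard labels use a 0.5 probability threshold for binary models and
argmax (ties to the lowest class index) for multiclass.

## Descriptors and fingerprints

The descriptor block is the named open set `rdkit-core` (16 RDKit 2D
descriptors: MolWt, MolLogP, TPSA, H-bond donors/acceptors, rotatable
bonds, ring counts, BertzCT, connectivity indices, …). The original
commercial descriptor blocks (QikProp, ADMETlab, Canvas topological)
are not enumerable or licensable here; the architecture is
feature-count agnostic, so an open set preserves the method while
keeping the package reproducible. Fingerprints are the public 166-key
MACCS catalogue (RDKit emits 167 positions with bit 0 permanently
unset; the leading bit is dropped by default). Missing descriptor
values are imputed with training-set medians; columns that are all-NaN
on the training set are dropped with a logged manifest. Standardization
uses training mean and population SD; constant columns map to 0.

## Baselines, ensemble, tuning

Baselines (Random Forest, Bagging over decision trees, AdaBoost, SVM)
are scikit-learn estimators behind a uniform probability contract:
binary models return an `(n, 1)` column of P(toxic), multiclass an
`(n, C)` row-stochastic matrix. The ensemble combines Random Forest,
Bagging and AdaBoost by the elementwise arithmetic mean of their
probability matrices — the simplest combiner consistent with averaging
ensemble probabilities; every combined entry lies within the member
extrema, and the hybrid network is reported separately, not inside the
ensemble. Alternative combiners can be passed by composing
`ensemble_proba` manually.

Hyperparameter search uses a compact Tree-structured Parzen Estimator
written for this package (no TPE library is a dependency): random
startup trials, a γ=0.25 quantile split of observed losses into
good/bad sets, independent one-dimensional Parzen (Gaussian-mixture)
densities per parameter with a spread-based bandwidth plus a 10%
uniform floor, and candidate selection by the good/bad density ratio.
The objective is `1 − validation AUC` — AUC rather than accuracy
because class imbalance makes accuracy saturate on the majority class.
Failed trials are logged with infinite loss, never silently dropped.

## Evaluation protocol

Metrics: accuracy, sensitivity TP/(TP+FN), specificity TN/(TN+FP),
precision TP/(TP+FP) at the 0.5 threshold (zero denominators return 0
with a warning so aggregates stay finite), and AUC under the
Mann–Whitney convention (ties credited ½). The multiclass headline is
the micro-averaged AUC: one-hot labels and probability matrices are
flattened into one binary ranking problem, which weights every
(sample, class) decision equally instead of over-weighting minority
dose categories as macro averaging would. Note the flattened statistic
is not identical to the binary AUC even for two complementary columns —
cross-column pairs enter the count — so the two are reported as what
they are.

The protocol draws `n_repeats` independent Monte-Carlo train/test
splits (seed = master seed + repeat index; both a 20% fraction and a
fixed test count are supported), trains every model from scratch per
repeat, and aggregates per-run metrics by mean and population SD.
Failed repeats are recorded and mark the report partial. Oversampling,
when configured, duplicates training rows of targeted classes by
drawing with replacement until target counts are met exactly — rows are
repeated, never modified — and is applied inside each repeat, after the
split, so duplicates never straddle the train/test boundary.

## Synthetic data generator

The generator emulates the statistical shape of curated acute-toxicity
tables: a SMILES string, a positive continuous LD50, route/species
tags, and a descriptor block correlated with the label. SMILES come
from a deliberately tiny valence-safe grammar — linear C/O/N chains of
4–10 heavy atoms with methyl branches and C=C units attached only to
carbons with spare valence — so every string is chemically valid by
construction and fixtures never depend on a chemistry backend's
tolerance. The toxicity motif is a terminal nitrile fragment `C#N`
(attachable to any chain terminus without valence violations, and the
only source of the `#` character, so motif detection by substring is
unambiguous).

LD50 is log-normal: log₁₀(LD50) ~ Normal(μ + δ·motif, σ) with defaults
μ = 2.5 (≈316 mg/kg), σ = 0.30 and δ = −1.0 for motif carriers at
prevalence 0.5. Dose data are positive and right-skewed, which
log-normality captures, and the additive log-scale shift makes the
planted effect analytically checkable by a two-sample mean comparison.
With these defaults the two class-conditional dose distributions are
separated by ≈3.3σ, so a classifier that recovers the motif attains AUC
≈ 0.95 against labels split at the mixture median — a strong,
near-separable signal appropriate for capacity checks. The descriptor
block has 6 signal columns (unit weight × `descriptor_signal` × motif
indicator + Gaussian noise, SD 0.5) and 4 pure-noise columns; setting
`descriptor_signal = 0` confines the signal to the SMILES view, the
regime in which the convolutional branch must carry the prediction
alone. `generate_imbalanced` rejection-samples until a requested
nontoxic:toxic ratio (1:1 up to ~8:1) is met within 5%.

What the generator does **not** emulate: real chemical diversity
(rings beyond none, charges, stereochemistry, heteroaromatics),
realistic descriptor covariance, assay noise structure, or any
chemically meaningful structure–toxicity mechanism. Passing tests
therefore demonstrate that the pipeline recovers a planted signal under
controlled conditions — not that the model predicts real-world
toxicity.

## Problem sizes and numerical choices

The planted-signal capacity checks run at n = 2000 with a reduced
network (one convolution block of 16 filters, hidden width 32, 30
epochs, batch 64) — the signal is low-dimensional and a small network
recovers it fully, keeping the default suite fast. Probability-matrix
validity is enforced at 1e-6 row-sum tolerance; metric oracles agree to
1e-12; report aggregates equal per-run means to 1e-12. When shuffling
labels for permutation-null checks, the shuffle stream must be
independent of the split seed — reusing one seed for both makes the
permutations correlated and leaves "null" labels partially predictable
(observed as spuriously high null AUC during development).

## Known limitations

* Random splits can place near-duplicate molecules on both sides of the
  train/test boundary, overestimating generalization; cluster-based
  splits are out of scope.
* The NumPy network is CPU-only and sized for desk-scale corpora
  (thousands of chemicals, SMILES ≤ ~100 characters).
* Character-level tokenization splits two-letter elements; a
  token-level mode is out of scope.
* No SMILES canonicalization or validity checking happens in the codec
  (delegated to the descriptor backend); no SELFIES/InChI support.
* Macro-averaged AUC, calibration analysis and significance tests
  between models are intentionally absent.
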