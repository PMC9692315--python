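# smitox

Hybrid CNN+FFNN classification of dose-range chemical toxicity from
SMILES strings and molecular descriptors.

## The problem

Acute toxicity is summarized by the LD50 — the dose, in mg per kg body
weight, lethal to half the test animals; a *lower* LD50 means a *more*
toxic chemical. Given a table of chemicals annotated with LD50 values,
`smitox` builds binary (toxic / nontoxic at a dose cutoff, e.g.
500 mg/kg) and four-category dose-range classifiers
([0,50), [50,500), [500,1000), [1000,∞) mg/kg) intended for toxicologists
and cheminformaticians who need fast in-silico prioritization instead of
animal assays.

## The model

Each chemical is presented to the classifier in two views:

* **Structure view.** The SMILES string is tokenized per character
  through a dictionary `D = {c₁:1, …, c_M:M}` and one-hot encoded into an
  `L × M` binary matrix (`L` = maximum SMILES length, all-zero rows pad
  the tail); a corpus of `K` chemicals becomes a `K × L × M` tensor. A
  convolutional branch (Conv1D → ReLU `max(0, x)` → max pooling, per
  block) reads this tensor. An optional second convolutional branch
  reads a MACCS-key fingerprint bit vector.
* **Property view.** A fixed-width molecular descriptor vector
  (an open RDKit 2D descriptor set, or user-supplied columns) is
  standardized with train-set statistics and read by a feed-forward
  (MLP) branch of fully connected ReLU layers.

The branch outputs are concatenated and a single dense head produces
the prediction — a sigmoid unit for binary labels, a softmax over dose
categories otherwise — trained by cross-entropy with adaptive-moment
gradient descent (implemented in NumPy; deterministic given a seed).
Around the core model the package provides: Random Forest / Bagging /
AdaBoost / SVM baselines with a uniform probability contract, an
ensemble that averages member class probabilities elementwise,
random oversampling with replacement for imbalanced classes,
Tree-structured Parzen Estimator hyperparameter search minimizing
`1 − validation AUC`, and a repeated Monte-Carlo split protocol
reporting accuracy, AUC (Mann–Whitney; micro-averaged one-vs-rest for
multiclass), sensitivity, specificity and precision.

A synthetic-data module generates valid-by-construction SMILES with a
planted structure–toxicity association (a nitrile motif shifts
log₁₀ LD50) so every stage is testable offline; see
[`docs/methods.md`](docs/methods.md).

## Worked example

Train the hybrid classifier on a planted-signal synthetic set of 2000
chemicals, labeled toxic/nontoxic at the mixture-median LD50:

```python
import numpy as np
from smitox import (GeneratorConfig, HybridConfig, binary_metrics,
                    build_dictionary, encode_batch, generate_dataset,
                    label_binary, random_split)
from smitox.model import HybridToxicityModel

cfg = GeneratorConfig(n=2000, motif_effect=-1.0, seed=7)
dataset = label_binary(generate_dataset(cfg), cutoff=cfg.median_ld50())
train, test = random_split(dataset, 0.2, seed=7)

dictionary = build_dictionary(dataset.smiles)
L = max(len(s) for s in dataset.smiles)
descriptors = lambda part: np.vstack([r.descriptors for r in part.records])

model = HybridToxicityModel(
    encode_batch(train.smiles, dictionary, L), descriptors(train), train.labels,
    config=HybridConfig(conv_blocks=((16, 4, 2),), ffnn_hidden=(32,),
                        epochs=30, batch_size=64))
results = model.fit(seed=7)
print(results.summary())

proba = results.predict_proba(encode_batch(test.smiles, dictionary, L),
                              descriptors(test))
for name, value in binary_metrics(test.labels, proba[:, 0]).items():
    print(f"{name:<12}{value:.3f}")
```

Output:

```
Hybrid CNN+FFNN toxicity classifier
==============================================
classes:            2 (sigmoid head)
SMILES tensor:      L=22, M=7
conv blocks:        [(16, 4, 2)]
fingerprint branch: off
descriptors:        10
FFNN hidden:        [32] (dropout 0.25)
parameters:         993
epochs run:         15 / 30
final train loss:   0.2125
best val AUC:       0.9647
seed:               7
accuracy    0.915
auc         0.938
sensitivity 0.954
specificity 0.878
precision   0.882
```

The generator plants a −1.0 log₁₀ shift in LD50 for nitrile-bearing
molecules, so a held-out AUC near 0.94 means the network recovered the
planted structure–toxicity association from the SMILES and descriptor
views; sensitivity 0.954 is the fraction of truly toxic test chemicals
ranked past the 0.5 probability threshold.

The same workflow is available from the shell:

```bash
smitox synth --n 2000 --seed 7 --out chems.csv
smitox train chems.csv --cutoff 100 --epochs 30 --out-dir model/
smitox predict model/ chems.csv --out predictions.csv
smitox run --config experiment.yaml --out-dir results/
```

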