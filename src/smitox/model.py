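"""Hybrid CNN+FFNN toxicity classifier, baseline learners, and the ensemble.

The hybrid network reads two (optionally three) views of each chemical:

* a convolutional branch over the one-hot encoded SMILES tensor
  (convolution -> ReLU -> max pooling per block, then flattened),
* an optional second convolutional branch over the fingerprint bit
  vector, treated as a length-F single-channel sequence,
* a feed-forward branch of fully connected ReLU layers over the
  descriptor vector.

The branch outputs are concatenated and a single dense head produces the
class scores — a sigmoid unit for binary toxic/nontoxic, a softmax over
the dose-range categories otherwise.  Training minimizes cross-entropy
with adaptive-moment gradient descent and early-stops on validation AUC.

The module follows a model/results split: :class:`HybridToxicityModel`
is built from data, ``fit()`` returns :class:`HybridToxicityResults`
carrying the trained network, training history and a ``summary()``
table.  Thin functional wrappers (:func:`build_hybrid`,
:func:`train_hybrid`, :func:`train_baseline`, :func:`ensemble_proba`)
expose the same operations.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ._nn import (
    Adam,
    Branch,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    MaxPool1D,
    ReLU,
    binary_cross_entropy,
    categorical_cross_entropy,
    sigmoid,
    softmax,
)
from .codec import EncodedSmilesTensor
from .evaluation import micro_auc_multiclass, roc_auc
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "HybridConfig",
    "HybridNetwork",
    "HybridToxicityModel",
    "HybridToxicityResults",
    "build_hybrid",
    "train_hybrid",
    "train_baseline",
    "BaselineModel",
    "ensemble_proba",
    "validate_probabilities",
]


@dataclass(frozen=True)
class HybridConfig:
    """Architecture and training hyperparameters of the hybrid network.

    ``conv_blocks`` is a sequence of (n_filters, kernel_length,
    pool_length) triples — filter counts may differ per layer.  The head
    is chosen from the number of classes at build time (sigmoid for 2,
    softmax otherwise), so it is never inconsistent with the data.
    """

    conv_blocks: tuple[tuple[int, int, int], ...] = ((64, 4, 2), (128, 4, 2))
    ffnn_hidden: tuple[int, ...] = (256, 128)
    use_fingerprint_branch: bool = False
    dropout_rate: float = 0.25
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    patience: int = 10
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_blocks) < 1:
            raise ValueError("at least one convolution block is required")
        if len(self.ffnn_hidden) < 1:
            raise ValueError("at least one hidden layer is required")
        for f, k, p in self.conv_blocks:
            if min(f, k, p) < 1:
                raise ValueError("conv block dimensions must be positive")


def validate_probabilities(p: np.ndarray, n_classes: int,
                           atol: float = 1e-6) -> None:
    """Raise unless ``p`` is a valid probability matrix for ``n_classes``."""
    p = np.asarray(p)
    if p.ndim != 2:
        raise ValueError("probability matrix must be 2-D")
    if p.min() < -atol or p.max() > 1 + atol:
        raise ValueError("probabilities must lie in [0, 1]")
    if n_classes > 2 and not np.allclose(p.sum(axis=1), 1.0, atol=atol):
        raise ValueError("multiclass probability rows must sum to 1")


def _conv_branch(c_in: int, length: int, blocks, rng) -> tuple[Branch, int]:
    layers: list = []
    L = length
    for n_filters, kernel, pool in blocks:
        layers += [Conv1D(c_in, n_filters, kernel, rng), ReLU()]
        L = L - kernel + 1
        if L < 1:
            raise ValueError("SMILES length too short for the conv stack")
        layers.append(MaxPool1D(pool))
        L //= pool
        if L < 1:
            raise ValueError("SMILES length too short for the pooling stack")
        c_in = n_filters
    layers.append(Flatten())
    return Branch(layers), L * c_in


class HybridNetwork:
    """The assembled multi-branch network (untrained until ``fit``)."""

    def __init__(
        self,
        config: HybridConfig,
        max_length: int,
        alphabet_size: int,
        n_descriptors: int,
        n_fingerprint_bits: int | None = None,
        n_classes: int = 2,
    ) -> None:
        if min(max_length, alphabet_size, n_descriptors) < 1:
            raise ValueError("input dimensions must be positive")
        if n_classes < 2:
            raise ValueError("need at least two classes")
        if config.use_fingerprint_branch and not n_fingerprint_bits:
            raise ValueError(
                "use_fingerprint_branch requires n_fingerprint_bits"
            )
        self.config = config
        self.n_classes = n_classes
        self.dims = (max_length, alphabet_size, n_descriptors,
                     n_fingerprint_bits if config.use_fingerprint_branch else None)
        rng = np.random.default_rng(config.seed)
        self.smiles_branch, w_smiles = _conv_branch(
            alphabet_size, max_length, config.conv_blocks, rng)
        w_total = w_smiles
        self.fp_branch = None
        if config.use_fingerprint_branch:
            self.fp_branch, w_fp = _conv_branch(
                1, n_fingerprint_bits, config.conv_blocks, rng)
            w_total += w_fp
        ffnn: list = []
        d = n_descriptors
        for width in config.ffnn_hidden:
            ffnn += [Dense(d, width, rng), ReLU(),
                     Dropout(config.dropout_rate, rng)]
            d = width
        self.desc_branch = Branch(ffnn)
        w_total += d
        self.head = Dense(w_total, 1 if n_classes == 2 else n_classes, rng)
        self._rng = rng
        self._widths = (w_smiles,
                        w_total - w_smiles - d if self.fp_branch else 0, d)

    # -- forward / backward -------------------------------------------------

    @property
    def _all_params(self) -> list[np.ndarray]:
        parts = self.smiles_branch.params + self.desc_branch.params
        if self.fp_branch is not None:
            parts += self.fp_branch.params
        return parts + self.head.params

    @property
    def _all_grads(self) -> list[np.ndarray]:
        parts = self.smiles_branch.grads + self.desc_branch.grads
        if self.fp_branch is not None:
            parts += self.fp_branch.grads
        return parts + self.head.grads

    def _coerce(self, smiles, descriptors, fingerprints):
        x_s = smiles.data if isinstance(smiles, EncodedSmilesTensor) else smiles
        x_s = np.asarray(x_s, dtype=float)
        x_d = descriptors.values if isinstance(descriptors, FeatureMatrix) else descriptors
        x_d = np.asarray(x_d, dtype=float)
        if x_s.shape[0] != x_d.shape[0]:
            raise ValueError("SMILES tensor and descriptor matrix row counts differ")
        x_f = None
        if self.fp_branch is not None:
            if fingerprints is None:
                raise ValueError("this network requires a fingerprint input")
            x_f = fingerprints.values if isinstance(fingerprints, FeatureMatrix) else fingerprints
            x_f = np.asarray(x_f, dtype=float)[:, :, None]  # (n, F, 1)
            if x_f.shape[0] != x_s.shape[0]:
                raise ValueError("fingerprint row count differs")
        return x_s, x_d, x_f

    def _forward(self, x_s, x_d, x_f, training: bool) -> np.ndarray:
        parts = [self.smiles_branch.forward(x_s, training)]
        if self.fp_branch is not None:
            parts.append(self.fp_branch.forward(x_f, training))
        parts.append(self.desc_branch.forward(x_d, training))
        self._split = np.cumsum([p.shape[1] for p in parts])[:-1]
        merged = np.concatenate(parts, axis=1)
        return self.head.forward(merged, training)

    def _backward(self, grad_logits: np.ndarray) -> None:
        grad = self.head.backward(grad_logits)
        pieces = np.split(grad, self._split, axis=1)
        self.smiles_branch.backward(pieces[0])
        if self.fp_branch is not None:
            self.fp_branch.backward(pieces[1])
        self.desc_branch.backward(pieces[-1])

    def predict_proba(self, smiles, descriptors, fingerprints=None) -> np.ndarray:
        """Class probabilities: (n, 1) for binary, (n, C) for multiclass."""
        x_s, x_d, x_f = self._coerce(smiles, descriptors, fingerprints)
        logits = self._forward(x_s, x_d, x_f, training=False)
        p = sigmoid(logits) if self.n_classes == 2 else softmax(logits)
        validate_probabilities(p, self.n_classes)
        return p

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for p in self._all_params:
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    # -- training -----------------------------------------------------------

    def fit(self, smiles, descriptors, labels, fingerprints=None,
            validation=None) -> dict:
        """Train in place; returns the per-epoch history.

        ``validation`` is an optional (smiles, descriptors, labels[,
        fingerprints]) tuple; when absent, ``validation_fraction`` rows
        are held out internally for early stopping on validation AUC.
        """
        cfg = self.config
        x_s, x_d, x_f = self._coerce(smiles, descriptors, fingerprints)
        y = np.asarray(labels, dtype=np.int64)
        if y.shape[0] != x_s.shape[0]:
            raise ValueError("label count differs from input rows")
        if y.min() < 0 or y.max() >= self.n_classes:
            raise ValueError(f"labels must lie in 0..{self.n_classes - 1}")

        if validation is not None:
            v = list(validation) + [None] * (4 - len(validation))
            vx_s, vx_d, vx_f = self._coerce(v[0], v[1], v[3])
            vy = np.asarray(v[2], dtype=np.int64)
        elif cfg.validation_fraction > 0 and x_s.shape[0] >= 20:
            n_val = max(1, int(round(x_s.shape[0] * cfg.validation_fraction)))
            perm = self._rng.permutation(x_s.shape[0])
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            vx_s, vx_d = x_s[val_idx], x_d[val_idx]
            vx_f = x_f[val_idx] if x_f is not None else None
            vy = y[val_idx]
            x_s, x_d, y = x_s[tr_idx], x_d[tr_idx], y[tr_idx]
            x_f = x_f[tr_idx] if x_f is not None else None
        else:
            vx_s = vy = vx_d = vx_f = None

        onehot = None
        if self.n_classes > 2:
            onehot = np.eye(self.n_classes)[y]

        optimizer = Adam(self._all_params, lr=cfg.learning_rate)
        history: dict = {"loss": [], "val_auc": []}
        best_auc, best_state, patience_left = -np.inf, None, cfg.patience
        n = x_s.shape[0]
        for epoch in range(cfg.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                logits = self._forward(
                    x_s[idx], x_d[idx],
                    x_f[idx] if x_f is not None else None, training=True)
                if self.n_classes == 2:
                    p = sigmoid(logits)
                    loss = binary_cross_entropy(p, y[idx])
                    grad = (p - y[idx][:, None]) / idx.size
                else:
                    p = softmax(logits)
                    loss = categorical_cross_entropy(p, onehot[idx])
                    grad = (p - onehot[idx]) / idx.size
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: loss={loss!r}, "
                        f"lr={cfg.learning_rate}, batch={cfg.batch_size}"
                    )
                self._backward(grad)
                optimizer.step(self._all_grads)
                epoch_loss += loss * idx.size
            history["loss"].append(epoch_loss / n)

            if vy is not None:
                val_p = self.predict_proba(vx_s, vx_d, vx_f)
                val_auc = self._auc(vy, val_p)
                history["val_auc"].append(val_auc)
                if val_auc > best_auc + 1e-12:
                    best_auc = val_auc
                    best_state = [p.copy() for p in self._all_params]
                    patience_left = cfg.patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        logger.info("early stop at epoch %d (best val AUC %.4f)",
                                    epoch, best_auc)
                        break
        if best_state is not None:
            for p, best in zip(self._all_params, best_state):
                p[...] = best
        return history

    def _auc(self, y: np.ndarray, p: np.ndarray) -> float:
        if self.n_classes == 2:
            if len(np.unique(y)) < 2:
                return 0.5
            return roc_auc(y, p[:, 0])
        return micro_auc_multiclass(np.eye(self.n_classes)[y], p)


# ---------------------------------------------------------------------------
# Model / Results objects


class HybridToxicityModel:
    """Hybrid classifier bound to its training data (model/results split).

    Parameters are data views of the same chemicals: the one-hot SMILES
    tensor, the descriptor matrix, integer class labels, and optionally
    a fingerprint bit matrix (used only when the config enables the
    fingerprint branch).
    """

    def __init__(self, smiles, descriptors, labels, fingerprints=None,
                 config: HybridConfig | None = None,
                 n_classes: int | None = None) -> None:
        self.smiles = smiles
        self.descriptors = descriptors
        self.fingerprints = fingerprints
        self.labels = np.asarray(labels, dtype=np.int64)
        self.config = config or HybridConfig()
        self.n_classes = n_classes or int(self.labels.max()) + 1
        if self.n_classes < 2:
            raise ValueError("need at least two classes")

    def fit(self, seed: int | None = None) -> "HybridToxicityResults":
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        x = self.smiles.data if isinstance(self.smiles, EncodedSmilesTensor) else np.asarray(self.smiles)
        d = self.descriptors.values if isinstance(self.descriptors, FeatureMatrix) else np.asarray(self.descriptors)
        fp_bits = None
        if cfg.use_fingerprint_branch:
            f = self.fingerprints.values if isinstance(self.fingerprints, FeatureMatrix) else np.asarray(self.fingerprints)
            fp_bits = f.shape[1]
        network = HybridNetwork(cfg, x.shape[1], x.shape[2], d.shape[1],
                                fp_bits, self.n_classes)
        history = network.fit(self.smiles, self.descriptors, self.labels,
                              self.fingerprints if cfg.use_fingerprint_branch else None)
        return HybridToxicityResults(self, network, history)


@dataclass
class HybridToxicityResults:
    """Fitted hybrid network plus its training history and diagnostics."""

    model: HybridToxicityModel
    network: HybridNetwork
    history: dict

    def predict_proba(self, smiles, descriptors, fingerprints=None) -> np.ndarray:
        return self.network.predict_proba(smiles, descriptors, fingerprints)

    def predict(self, smiles, descriptors, fingerprints=None,
                threshold: float = 0.5) -> np.ndarray:
        """Hard labels: 0.5 threshold for binary, argmax for multiclass
        (ties break to the lowest class index via argmax)."""
        p = self.predict_proba(smiles, descriptors, fingerprints)
        if self.network.n_classes == 2:
            return (p[:, 0] >= threshold).astype(np.int64)
        return p.argmax(axis=1)

    def summary(self) -> str:
        cfg = self.network.config
        L, M, D, F = self.network.dims
        lines = [
            "Hybrid CNN+FFNN toxicity classifier",
            "=" * 46,
            f"classes:            {self.network.n_classes} "
            f"({'sigmoid' if self.network.n_classes == 2 else 'softmax'} head)",
            f"SMILES tensor:      L={L}, M={M}",
            f"conv blocks:        {list(cfg.conv_blocks)}",
            f"fingerprint branch: {'on (%d bits)' % F if F else 'off'}",
            f"descriptors:        {D}",
            f"FFNN hidden:        {list(cfg.ffnn_hidden)} (dropout {cfg.dropout_rate})",
            f"parameters:         {sum(p.size for p in self.network._all_params):,}",
            f"epochs run:         {len(self.history['loss'])} / {cfg.epochs}",
            f"final train loss:   {self.history['loss'][-1]:.4f}",
        ]
        if self.history["val_auc"]:
            lines.append(f"best val AUC:       {max(self.history['val_auc']):.4f}")
        lines.append(f"seed:               {cfg.seed}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional surface


def build_hybrid(config: HybridConfig, max_length: int, alphabet_size: int,
                 n_descriptors: int, n_fingerprint_bits: int | None = None,
                 n_classes: int = 2) -> HybridNetwork:
    """Assemble an untrained hybrid network with explicit dimensions."""
    return HybridNetwork(config, max_length, alphabet_size, n_descriptors,
                         n_fingerprint_bits, n_classes)


def train_hybrid(network: HybridNetwork, smiles, descriptors, labels,
                 fingerprints=None, validation=None) -> tuple[HybridNetwork, dict]:
    """Train an assembled network; returns it with the epoch history."""
    history = network.fit(smiles, descriptors, labels, fingerprints, validation)
    return network, history


class DescriptorFFNN:
    """Descriptors-only feed-forward classifier (the FFNN branch alone).

    Shares layers, loss and optimizer with the hybrid network but reads
    only the descriptor vector — the comparator for quantifying what the
    SMILES convolution branch adds.
    """

    def __init__(self, config: HybridConfig, n_descriptors: int,
                 n_classes: int = 2) -> None:
        self.config = config
        self.n_classes = n_classes
        rng = np.random.default_rng(config.seed)
        layers: list = []
        d = n_descriptors
        for width in config.ffnn_hidden:
            layers += [Dense(d, width, rng), ReLU(),
                       Dropout(config.dropout_rate, rng)]
            d = width
        layers.append(Dense(d, 1 if n_classes == 2 else n_classes, rng))
        self.stack = Branch(layers)
        self._rng = rng

    def predict_proba(self, descriptors) -> np.ndarray:
        x = descriptors.values if isinstance(descriptors, FeatureMatrix) else np.asarray(descriptors, dtype=float)
        logits = self.stack.forward(x, training=False)
        p = sigmoid(logits) if self.n_classes == 2 else softmax(logits)
        validate_probabilities(p, self.n_classes)
        return p

    def fit(self, descriptors, labels) -> dict:
        cfg = self.config
        x = descriptors.values if isinstance(descriptors, FeatureMatrix) else np.asarray(descriptors, dtype=float)
        y = np.asarray(labels, dtype=np.int64)
        onehot = np.eye(self.n_classes)[y] if self.n_classes > 2 else None
        optimizer = Adam(self.stack.params, lr=cfg.learning_rate)
        history: dict = {"loss": []}
        n = x.shape[0]
        for epoch in range(cfg.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                logits = self.stack.forward(x[idx], training=True)
                if self.n_classes == 2:
                    p = sigmoid(logits)
                    loss = binary_cross_entropy(p, y[idx])
                    grad = (p - y[idx][:, None]) / idx.size
                else:
                    p = softmax(logits)
                    loss = categorical_cross_entropy(p, onehot[idx])
                    grad = (p - onehot[idx]) / idx.size
                if not np.isfinite(loss):
                    raise RuntimeError(f"FFNN diverged at epoch {epoch}")
                self.stack.backward(grad)
                optimizer.step(self.stack.grads)
                epoch_loss += loss * idx.size
            history["loss"].append(epoch_loss / n)
        return history


# ---------------------------------------------------------------------------
# Baseline learners


_BASELINES = ("random_forest", "bagging", "adaboost", "svm")


class BaselineModel:
    """Uniform probability contract over the scikit-learn baselines."""

    def __init__(self, kind: str, estimator, n_classes: int) -> None:
        self.kind = kind
        self.estimator = estimator
        self.n_classes = n_classes

    def predict_proba(self, features) -> np.ndarray:
        X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
        p = self.estimator.predict_proba(X)
        p = p[:, 1:2] if self.n_classes == 2 else p
        validate_probabilities(p, self.n_classes)
        return p

    def predict(self, features, threshold: float = 0.5) -> np.ndarray:
        p = self.predict_proba(features)
        if self.n_classes == 2:
            return (p[:, 0] >= threshold).astype(np.int64)
        return p.argmax(axis=1)


def train_baseline(kind: str, features, labels, params: dict | None = None,
                   seed: int = 0) -> BaselineModel:
    """Fit one of the comparison learners (RF, Bagging, AdaBoost, SVM)."""
    from sklearn.ensemble import (AdaBoostClassifier, BaggingClassifier,
                                  RandomForestClassifier)
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    if kind not in _BASELINES:
        raise ValueError(f"unknown baseline {kind!r}; choose from {_BASELINES}")
    params = dict(params or {})
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    y = np.asarray(labels, dtype=np.int64)
    if not np.isfinite(X).all():
        raise ValueError("baseline features must be finite (impute first)")
    if kind == "random_forest":
        est = RandomForestClassifier(
            n_estimators=params.pop("n_estimators", 200),
            random_state=seed, **params)
    elif kind == "bagging":
        est = BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=params.pop("n_estimators", 100),
            random_state=seed, **params)
    elif kind == "adaboost":
        est = AdaBoostClassifier(
            n_estimators=params.pop("n_estimators", 100),
            random_state=seed, **params)
    else:
        est = SVC(probability=True, random_state=seed, **params)
    est.fit(X, y)
    return BaselineModel(kind, est, int(y.max()) + 1)


def ensemble_proba(members: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise arithmetic mean of member probability matrices.

    The combiner for the RF/Bagging/AdaBoost ensemble; every output entry
    is bracketed by the member extrema by construction.
    """
    if len(members) < 2:
        raise ValueError("an ensemble needs at least two members")
    mats = [np.asarray(m, dtype=float) for m in members]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("ensemble members must share one shape")
    return np.mean(mats, axis=0)
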