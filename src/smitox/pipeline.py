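"""End-to-end experiment pipeline and persisted model bundles.

``run_experiment`` wires the stages together — load or generate
chemicals, filter by route/species, label by dose scheme, build the
SMILES dictionary over the full corpus (as the tokenizer protocol
prescribes), then for each requested model run the repeated random-split
protocol: split, optionally oversample the training classes, fit
train-only feature preprocessing, train, and score the held-out set.
Every run writes a manifest (config, seeds, package version) sufficient
to reproduce the report.

``HybridBundle`` is the on-disk form of a trained hybrid classifier:
architecture config, weights, SMILES dictionary and maximum length,
feature manifest, imputation medians and scaler statistics — enough for
bit-reproducible reload and prediction on new chemicals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .codec import (OutOfVocabularyError, SmilesDictionary, build_dictionary,
                    encode_batch, encode_smiles)
from .data import (ChemicalRecord, LabeledDataset, filter_records,
                   label_binary, label_multiclass, oversample, read_chemicals)
from .evaluation import EvaluationReport, repeated_evaluation
from .features import (FeatureMatrix, MedianImputer, Scaler,
                       compute_descriptors, fit_scaler)
from .model import (HybridConfig, HybridNetwork, ensemble_proba,
                    train_baseline)
from .synthetic import GeneratorConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["run_experiment", "predict", "HybridBundle", "featurize_records",
           "train_hybrid_pipeline"]

ENSEMBLE_MEMBERS = ("random_forest", "bagging", "adaboost")
MODEL_NAMES = ("hybrid",) + ENSEMBLE_MEMBERS + ("svm", "ensemble")


def featurize_records(records: Sequence[ChemicalRecord],
                      descriptor_set: str = "rdkit-core") -> FeatureMatrix:
    """Descriptor matrix for a record list.

    Records that already carry a descriptor vector (synthetic fixtures,
    precomputed columns) are used as-is when every record has one;
    otherwise descriptors are computed from SMILES.
    """
    if all(r.descriptors is not None for r in records):
        values = np.vstack([np.asarray(r.descriptors, dtype=float) for r in records])
        names = tuple(f"d{i}" for i in range(values.shape[1]))
        return FeatureMatrix(values, names, "descriptors")
    return compute_descriptors(records, descriptor_set)


# ---------------------------------------------------------------------------
# Trained-model bundle


@dataclasses.dataclass
class HybridBundle:
    """A trained hybrid classifier with its full preprocessing state."""

    network: HybridNetwork
    dictionary: SmilesDictionary
    max_length: int
    imputer: MedianImputer
    scaler: Scaler
    class_names: tuple[str, ...]
    descriptor_set: str = "rdkit-core"

    def predict_proba_records(self, records: Sequence[ChemicalRecord]) -> np.ndarray:
        smiles = encode_batch([r.smiles for r in records], self.dictionary,
                              self.max_length)
        desc = self.scaler.transform(
            self.imputer.transform(featurize_records(records, self.descriptor_set)))
        return self.network.predict_proba(smiles, desc)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg = self.network.config
        (out / "config.json").write_text(json.dumps({
            "hybrid_config": dataclasses.asdict(cfg),
            "n_classes": self.network.n_classes,
            "max_length": self.max_length,
            "alphabet_size": self.dictionary.size,
            "n_descriptors": self.network.dims[2],
            "n_fingerprint_bits": self.network.dims[3],
            "class_names": list(self.class_names),
            "descriptor_set": self.descriptor_set,
        }, indent=2))
        self.dictionary.to_text(out / "dictionary.txt")
        self.imputer.to_json(out / "imputer.json")
        self.scaler.to_json(out / "scaler.json")
        np.savez(out / "weights.npz",
                 **{f"w{i}": p for i, p in enumerate(self.network._all_params)})

    @classmethod
    def load(cls, bundle_dir: str | Path) -> "HybridBundle":
        src = Path(bundle_dir)
        required = ["config.json", "dictionary.txt", "imputer.json",
                    "scaler.json", "weights.npz"]
        missing = [f for f in required if not (src / f).exists()]
        if missing:
            raise FileNotFoundError(f"incomplete bundle {src}: missing {missing}")
        blob = json.loads((src / "config.json").read_text())
        hc = blob["hybrid_config"]
        hc["conv_blocks"] = tuple(tuple(b) for b in hc["conv_blocks"])
        hc["ffnn_hidden"] = tuple(hc["ffnn_hidden"])
        cfg = HybridConfig(**hc)
        network = HybridNetwork(cfg, blob["max_length"], blob["alphabet_size"],
                                blob["n_descriptors"], blob["n_fingerprint_bits"],
                                blob["n_classes"])
        with np.load(src / "weights.npz") as weights:
            for i, p in enumerate(network._all_params):
                p[...] = weights[f"w{i}"]
        return cls(
            network=network,
            dictionary=SmilesDictionary.from_text(src / "dictionary.txt"),
            max_length=blob["max_length"],
            imputer=MedianImputer.from_json(src / "imputer.json"),
            scaler=Scaler.from_json(src / "scaler.json"),
            class_names=tuple(blob["class_names"]),
            descriptor_set=blob["descriptor_set"],
        )


def train_hybrid_pipeline(
    train: LabeledDataset,
    dictionary: SmilesDictionary,
    max_length: int,
    config: HybridConfig,
    seed: int,
    descriptor_set: str = "rdkit-core",
) -> HybridBundle:
    """Fit preprocessing on the training set only, then train the network."""
    cfg = dataclasses.replace(config, seed=seed)
    desc_raw = featurize_records(train.records, descriptor_set)
    imputer = MedianImputer().fit(desc_raw)
    desc_imp = imputer.transform(desc_raw)
    scaler = fit_scaler(desc_imp)
    desc = scaler.transform(desc_imp)
    smiles = encode_batch(train.smiles, dictionary, max_length)
    network = HybridNetwork(cfg, max_length, dictionary.size, desc.n_features,
                            n_classes=train.n_classes)
    network.fit(smiles, desc, train.labels)
    return HybridBundle(network, dictionary, max_length, imputer, scaler,
                        train.scheme.class_names, descriptor_set)


# ---------------------------------------------------------------------------
# Model factories for the repeated-split protocol


def make_model_factory(
    name: str,
    dictionary: SmilesDictionary,
    max_length: int,
    hybrid_config: HybridConfig,
    descriptor_set: str = "rdkit-core",
    oversample_targets: Mapping[int, int] | None = None,
):
    """Factory conforming to the ``repeated_evaluation`` protocol."""
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")

    def factory(train: LabeledDataset, seed: int):
        if oversample_targets is not None:
            train = oversample(train, oversample_targets, seed)
        if name == "hybrid":
            bundle = train_hybrid_pipeline(train, dictionary, max_length,
                                           hybrid_config, seed, descriptor_set)
            return lambda test: bundle.predict_proba_records(test.records)

        desc_raw = featurize_records(train.records, descriptor_set)
        imputer = MedianImputer().fit(desc_raw)
        desc_imp = imputer.transform(desc_raw)
        scaler = fit_scaler(desc_imp)
        desc = scaler.transform(desc_imp)

        def test_features(test: LabeledDataset) -> FeatureMatrix:
            return scaler.transform(
                imputer.transform(featurize_records(test.records, descriptor_set)))

        if name == "ensemble":
            members = [train_baseline(k, desc, train.labels, seed=seed)
                       for k in ENSEMBLE_MEMBERS]
            def scorer(test: LabeledDataset) -> np.ndarray:
                X = test_features(test)
                return ensemble_proba([m.predict_proba(X) for m in members])
            return scorer
        baseline = train_baseline(name, desc, train.labels, seed=seed)
        return lambda test: baseline.predict_proba(test_features(test))

    return factory


# ---------------------------------------------------------------------------
# run_experiment


def _load_dataset(spec: Mapping) -> list[ChemicalRecord]:
    if "synthetic" in spec:
        return generate_dataset(GeneratorConfig(**spec["synthetic"]))
    if "path" in spec:
        return read_chemicals(spec["path"], format=spec.get("format"))
    raise ValueError("dataset must declare either 'synthetic' or 'path'")


def _label(records: Sequence[ChemicalRecord], spec: Mapping) -> LabeledDataset:
    kind = spec.get("kind")
    if kind == "binary":
        return label_binary(records, cutoff=spec["cutoff"])
    if kind in ("multiclass", "categorical"):
        return label_multiclass(records, boundaries=spec.get(
            "boundaries", (50.0, 500.0, 1000.0)))
    raise ValueError(f"labeling.kind must be 'binary' or 'multiclass', got {kind!r}")


def run_experiment(config: Mapping | str | Path,
                   out_dir: str | Path | None = None) -> dict:
    """Execute a full configured experiment; returns reports per model.

    ``config`` is a mapping (or path to a YAML/JSON file) with keys
    ``dataset``, ``labeling``, ``models``, ``n_repeats``, ``test_size``,
    ``seed`` and optional ``filter``, ``oversample``, ``hybrid``,
    ``descriptor_set``.  Re-running with an identical config reproduces
    the reports exactly.
    """
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    for key in ("dataset", "labeling", "models"):
        if key not in config:
            raise ValueError(f"experiment config is missing the {key!r} section")

    seed = int(config.get("seed", 0))
    records = _load_dataset(config["dataset"])
    if "filter" in config:
        flt = config["filter"]
        records = filter_records(
            records,
            route=set(flt["route"]) if "route" in flt else None,
            species=set(flt["species"]) if "species" in flt else None,
        )
    dataset = _label(records, config["labeling"])
    dictionary = build_dictionary(dataset.smiles)
    max_length = max(len(s) for s in dataset.smiles)

    hybrid_cfg = HybridConfig(**{
        **config.get("hybrid", {}),
        "conv_blocks": tuple(tuple(b) for b in config.get("hybrid", {}).get(
            "conv_blocks", HybridConfig().conv_blocks)),
        "ffnn_hidden": tuple(config.get("hybrid", {}).get(
            "ffnn_hidden", HybridConfig().ffnn_hidden)),
    })
    targets = None
    if "oversample" in config:
        targets = {int(k): int(v) for k, v in config["oversample"]["targets"].items()}

    reports: dict[str, EvaluationReport] = {}
    for name in config["models"]:
        factory = make_model_factory(
            name, dictionary, max_length, hybrid_cfg,
            config.get("descriptor_set", "rdkit-core"), targets)
        reports[name] = repeated_evaluation(
            dataset, factory,
            n_repeats=int(config.get("n_repeats", 10)),
            test_size=config.get("test_size", 0.2),
            master_seed=seed,
        )
        logger.info("%s: %s", name, reports[name].summary())

    manifest = {
        "config": json.loads(json.dumps(config, default=str)),
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest(),
        "seed": seed,
        "n_records": len(dataset),
        "class_counts": {str(k): v for k, v in dataset.class_counts().items()},
        "max_length": max_length,
        "alphabet_size": dictionary.size,
        "package_version": __version__,
    }
    result = {"reports": reports, "manifest": manifest}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for name, report in reports.items():
            report.to_json(out / f"report_{name}.json")
            report.to_csv(out / f"report_{name}.csv")
        logger.info("artifacts written to %s", out)
    return result


# ---------------------------------------------------------------------------
# Prediction on new chemicals


def predict(bundle_dir: str | Path, input_path: str | Path,
            out_path: str | Path) -> pd.DataFrame:
    """Predict class probabilities and hard labels for a chemicals file.

    Rows whose SMILES is out-of-vocabulary or longer than the training
    maximum are flagged in an ``error`` column; other rows are predicted
    normally.
    """
    bundle = HybridBundle.load(bundle_dir)
    records = read_chemicals(input_path)
    n_classes = bundle.network.n_classes
    prob_cols = (["p_toxic"] if n_classes == 2
                 else [f"p_{c}" for c in bundle.class_names])
    rows = []
    for rec in records:
        row: dict = {"id": rec.id, "smiles": rec.smiles, "error": ""}
        try:
            smiles = encode_smiles(rec.smiles, bundle.dictionary,
                                   bundle.max_length)[None, :, :]
            desc = bundle.scaler.transform(bundle.imputer.transform(
                featurize_records([rec], bundle.descriptor_set)))
            p = bundle.network.predict_proba(smiles, desc)[0]
            for col, value in zip(prob_cols, p):
                row[col] = float(value)
            if n_classes == 2:
                row["label"] = int(p[0] >= 0.5)
            else:
                row["label"] = int(np.argmax(p))
        except (OutOfVocabularyError, ValueError) as exc:
            row.update({col: np.nan for col in prob_cols})
            row["label"] = -1
            row["error"] = str(exc)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out_path, index=False)
    return df
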