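"""Molecular descriptor vectors, MACCS-key fingerprints, and train-fitted scaling.

Descriptors come from an open 2D descriptor set computed with RDKit; the
fingerprint block is the public 166-key MACCS catalogue.  Both are pure
functions of the (canonicalized) molecular graph, so equivalent SMILES
spellings of one molecule yield identical rows.  Imputation medians and
standardization statistics are always fitted on training rows only and
persisted, so held-out data never leak into the preprocessing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ChemicalRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "DESCRIPTOR_SETS",
    "compute_descriptors",
    "compute_fingerprint",
    "MedianImputer",
    "Scaler",
    "fit_scaler",
    "apply_scaler",
]

# Named 2D descriptor sets (RDKit Descriptors module function names).
DESCRIPTOR_SETS: dict[str, tuple[str, ...]] = {
    "rdkit-core": (
        "MolWt",
        "HeavyAtomCount",
        "MolLogP",
        "TPSA",
        "NumHDonors",
        "NumHAcceptors",
        "NumRotatableBonds",
        "RingCount",
        "NumAromaticRings",
        "FractionCSP3",
        "LabuteASA",
        "BertzCT",
        "Chi0",
        "Chi1",
        "HallKierAlpha",
        "MolMR",
    ),
}


@dataclass(frozen=True)
class FeatureMatrix:
    """n_records x n_features real matrix with named, order-stable columns."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    provenance: str  # "descriptors" | "fingerprint"
    failed_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[1] != len(self.feature_names):
            raise ValueError("values width must match feature_names")
        if self.provenance == "fingerprint":
            finite = v[np.isfinite(v)]
            if not np.isin(finite, (0.0, 1.0)).all():
                raise ValueError("fingerprint matrices may contain only 0/1")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, columns=list(self.feature_names)).to_csv(
            path, index=False
        )


def _mol_from_smiles(smiles: str):
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    return Chem.MolFromSmiles(smiles)


def compute_descriptors(
    records: Sequence[ChemicalRecord],
    descriptor_set: str = "rdkit-core",
) -> FeatureMatrix:
    """One descriptor row per record; unparsable SMILES become NaN rows.

    The indices of failed rows are reported on the result and logged;
    downstream imputation (see :class:`MedianImputer`) fills them from
    training-set medians.
    """
    if descriptor_set not in DESCRIPTOR_SETS:
        raise KeyError(
            f"unknown descriptor_set {descriptor_set!r}; "
            f"available: {sorted(DESCRIPTOR_SETS)}"
        )
    from rdkit.Chem import Descriptors

    names = DESCRIPTOR_SETS[descriptor_set]
    funcs = [getattr(Descriptors, n) for n in names]
    values = np.full((len(records), len(names)), np.nan)
    failed: list[int] = []
    for i, rec in enumerate(records):
        mol = _mol_from_smiles(rec.smiles)
        if mol is None:
            failed.append(i)
            continue
        values[i] = [f(mol) for f in funcs]
    if failed:
        logger.warning("descriptors: %d/%d SMILES failed to parse (indices %s...)",
                       len(failed), len(records), failed[:5])
    if len(failed) == len(records):
        raise ValueError("no parseable SMILES in input")
    return FeatureMatrix(values, names, "descriptors", tuple(failed))


def compute_fingerprint(
    records: Sequence[ChemicalRecord], n_bits: int = 166
) -> FeatureMatrix:
    """Public MACCS-key fingerprints, one bit row per record.

    RDKit emits 167 positions with bit 0 permanently unset; the default
    drops it, returning the canonical 166 keys.
    """
    if n_bits not in (166, 167):
        raise ValueError("n_bits must be 166 (canonical keys) or 167 (raw RDKit)")
    from rdkit.Chem import MACCSkeys

    values = np.full((len(records), n_bits), np.nan)
    failed: list[int] = []
    offset = 167 - n_bits
    for i, rec in enumerate(records):
        mol = _mol_from_smiles(rec.smiles)
        if mol is None:
            failed.append(i)
            continue
        bits = np.frombuffer(
            bytes(MACCSkeys.GenMACCSKeys(mol).ToBitString(), "ascii"), dtype=np.uint8
        ) - ord("0")
        values[i] = bits[offset:]
    if len(failed) == len(records):
        raise ValueError("no parseable SMILES in input")
    names = tuple(f"maccs_{k}" for k in range(offset, 167))
    return FeatureMatrix(values, names, "fingerprint", tuple(failed))


class MedianImputer:
    """Column-median imputation fitted on training rows only.

    Columns that are all-NaN on the training set carry no information and
    are dropped; the manifest of dropped names is logged and persisted.
    """

    def __init__(self) -> None:
        self.medians_: np.ndarray | None = None
        self.keep_: np.ndarray | None = None
        self.dropped_: tuple[str, ...] = ()
        self.feature_names_: tuple[str, ...] = ()

    def fit(self, train: FeatureMatrix) -> "MedianImputer":
        if train.values.shape[0] == 0:
            raise ValueError("cannot fit imputer on an empty matrix")
        all_nan = np.all(np.isnan(train.values), axis=0)
        self.keep_ = ~all_nan
        self.dropped_ = tuple(
            n for n, drop in zip(train.feature_names, all_nan) if drop
        )
        if self.dropped_:
            logger.warning("dropping all-NaN columns: %s", self.dropped_)
        self.feature_names_ = tuple(
            n for n, keep in zip(train.feature_names, self.keep_) if keep
        )
        self.medians_ = np.nanmedian(train.values[:, self.keep_], axis=0)
        return self

    def transform(self, matrix: FeatureMatrix) -> FeatureMatrix:
        if self.medians_ is None:
            raise RuntimeError("imputer is not fitted")
        if matrix.n_features != len(self.keep_):
            raise ValueError("feature width mismatch with fitted imputer")
        values = matrix.values[:, self.keep_].copy()
        nan_mask = np.isnan(values)
        values[nan_mask] = np.broadcast_to(self.medians_, values.shape)[nan_mask]
        if matrix.provenance == "fingerprint":
            values = np.rint(values)  # keep imputed rows on the 0/1 lattice
        return FeatureMatrix(values, self.feature_names_, matrix.provenance,
                             matrix.failed_indices)

    def to_json(self, path: str | Path) -> None:
        if self.medians_ is None:
            raise RuntimeError("imputer is not fitted")
        Path(path).write_text(json.dumps({
            "medians": self.medians_.tolist(),
            "keep": self.keep_.astype(int).tolist(),
            "dropped": list(self.dropped_),
            "feature_names": list(self.feature_names_),
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "MedianImputer":
        blob = json.loads(Path(path).read_text())
        imp = cls()
        imp.medians_ = np.asarray(blob["medians"], dtype=float)
        imp.keep_ = np.asarray(blob["keep"], dtype=bool)
        imp.dropped_ = tuple(blob["dropped"])
        imp.feature_names_ = tuple(blob["feature_names"])
        return imp


@dataclass
class Scaler:
    """Column standardization with training statistics (population SD).

    Constant training columns map to exactly 0 rather than dividing by a
    zero spread.
    """

    mean_: np.ndarray
    scale_: np.ndarray
    feature_names: tuple[str, ...]

    def transform(self, matrix: FeatureMatrix) -> FeatureMatrix:
        if matrix.n_features != self.mean_.size:
            raise ValueError("feature width mismatch with fitted scaler")
        values = (matrix.values - self.mean_) / self.scale_
        return FeatureMatrix(values, matrix.feature_names, "descriptors",
                             matrix.failed_indices)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "feature_names": list(self.feature_names),
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Scaler":
        blob = json.loads(Path(path).read_text())
        return cls(np.asarray(blob["mean"]), np.asarray(blob["scale"]),
                   tuple(blob["feature_names"]))


def fit_scaler(train: FeatureMatrix) -> Scaler:
    if train.values.shape[0] == 0:
        raise ValueError("cannot fit scaler on an empty matrix")
    from sklearn.preprocessing import StandardScaler

    ss = StandardScaler().fit(train.values)
    return Scaler(ss.mean_.copy(), ss.scale_.copy(), train.feature_names)


def apply_scaler(scaler: Scaler, matrix: FeatureMatrix) -> FeatureMatrix:
    return scaler.transform(matrix)
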