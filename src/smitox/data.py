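"""Chemical records, file I/O, LD50 dose-range labeling, splits, oversampling.

LD50 is the dose (mg per kg body weight) lethal to half the test animals;
a *lower* LD50 means a *more* toxic chemical.  Binary labeling therefore
marks a record toxic (label 1) when its LD50 falls strictly below the
chosen cutoff; a record exactly at the cutoff is nontoxic, so that the
500 mg/kg binary scheme coarsens the four-category scheme exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ChemicalRecord",
    "LabelScheme",
    "LabeledDataset",
    "read_chemicals",
    "write_labeled_csv",
    "label_binary",
    "label_multiclass",
    "filter_records",
    "random_split",
    "oversample",
    "normalize_route",
]

# Free-text route-of-exposure synonyms, lowercased.  Unrecognized strings
# are kept verbatim (lowercased); they only match a filter that names them.
_ROUTE_SYNONYMS = {
    "oral": "oral",
    "po": "oral",
    "per os": "oral",
    "gavage": "oral",
    "ip": "ip",
    "intraperitoneal": "ip",
    "iv": "iv",
    "intravenous": "iv",
    "sc": "subcutaneous",
    "subcut": "subcutaneous",
    "subcutaneous": "subcutaneous",
}


def normalize_route(route: str | None) -> str | None:
    if route is None:
        return None
    key = route.strip().lower()
    return _ROUTE_SYNONYMS.get(key, key)


@dataclass(frozen=True)
class ChemicalRecord:
    """One chemical: identifier, SMILES, optional LD50 (mg/kg) and annotations."""

    id: str
    smiles: str
    ld50: float | None = None
    route: str | None = None
    species: str | None = None
    descriptors: np.ndarray | None = None
    fingerprint: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError(f"record {self.id!r}: SMILES must be non-empty")
        if self.ld50 is not None and not self.ld50 > 0:
            raise ValueError(f"record {self.id!r}: LD50 must be positive (mg/kg)")
        if self.fingerprint is not None:
            fp = np.asarray(self.fingerprint)
            if not np.isin(fp, (0, 1)).all():
                raise ValueError(f"record {self.id!r}: fingerprint bits must be 0/1")
        object.__setattr__(self, "route", normalize_route(self.route))


@dataclass(frozen=True)
class LabelScheme:
    """Metadata sufficient to recompute labels from LD50 exactly.

    ``kind`` is ``"binary"`` (one cutoff) or ``"categorical"`` (ordered
    boundaries defining half-open dose intervals, lowest dose = class 0).
    """

    kind: str
    cutoff: float | None = None
    boundaries: tuple[float, ...] | None = None
    class_names: tuple[str, ...] = ()

    def assign(self, ld50: float) -> int:
        if self.kind == "binary":
            return int(ld50 < self.cutoff)
        return int(np.searchsorted(np.asarray(self.boundaries), ld50, side="right"))


@dataclass(frozen=True)
class LabeledDataset:
    records: tuple[ChemicalRecord, ...]
    labels: np.ndarray
    scheme: LabelScheme

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "records", tuple(self.records))
        if len(labels) != len(self.records):
            raise ValueError("labels and records must have equal length")
        n_classes = len(self.scheme.class_names)
        if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
            raise ValueError(f"labels must lie in 0..{n_classes - 1}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_classes(self) -> int:
        return len(self.scheme.class_names)

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    def class_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    def recompute_labels(self) -> np.ndarray:
        """Re-derive labels from stored LD50s and scheme metadata."""
        return np.array([self.scheme.assign(r.ld50) for r in self.records])

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(indices)
        return LabeledDataset(
            records=tuple(self.records[i] for i in idx),
            labels=self.labels[idx],
            scheme=self.scheme,
        )


# ---------------------------------------------------------------------------
# I/O


def _parseable(smiles: str) -> bool:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    return Chem.MolFromSmiles(smiles) is not None


def read_chemicals(
    path: str | Path,
    format: str | None = None,
    ld50_tag: str = "LD50_mgkg",
    validate_smiles: bool = True,
) -> list[ChemicalRecord]:
    """Read chemicals from a ``.csv``, ``.smi`` or ``.sdf`` file.

    CSV needs a header naming at least ``smiles``; ``id``, ``ld50``,
    ``route`` and ``species`` columns are optional.  ``.smi`` holds one
    SMILES plus an optional identifier per line.  SDF LD50 is read from
    the ``ld50_tag`` property.  Rows whose SMILES does not parse are
    skipped and counted in the log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        rows = _rows_from_csv(path)
    elif fmt == "smi":
        rows = _rows_from_smi(path)
    elif fmt == "sdf":
        rows = _rows_from_sdf(path, ld50_tag)
    else:
        raise ValueError(f"unsupported format {fmt!r} (expected csv, smi or sdf)")

    records: list[ChemicalRecord] = []
    skipped = 0
    for row in rows:
        if validate_smiles and not _parseable(row["smiles"]):
            skipped += 1
            logger.warning("skipping %s: unparsable SMILES %r", row["id"], row["smiles"])
            continue
        records.append(ChemicalRecord(**row))
    if skipped:
        logger.info("read %d records, skipped %d unparsable from %s",
                    len(records), skipped, path)
    if not records:
        raise ValueError(f"no valid records in {path}")
    return records


def _rows_from_csv(path: Path) -> list[dict]:
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if "smiles" not in df.columns:
        raise ValueError(f"{path}: CSV header must name a 'smiles' column")
    rows = []
    for i, rec in enumerate(df.to_dict(orient="records")):
        rows.append(
            {
                "id": str(rec.get("id", f"row{i}")),
                "smiles": str(rec["smiles"]),
                "ld50": None if pd.isna(rec.get("ld50")) else float(rec["ld50"]),
                "route": None if pd.isna(rec.get("route")) else str(rec["route"]),
                "species": None if pd.isna(rec.get("species")) else str(rec["species"]),
            }
        )
    return rows


def _rows_from_smi(path: Path) -> list[dict]:
    rows = []
    for i, line in enumerate(path.read_text(encoding="utf-8").splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        rows.append({"id": parts[1] if len(parts) > 1 else f"mol{i}",
                     "smiles": parts[0]})
    return rows


def _rows_from_sdf(path: Path, ld50_tag: str) -> list[dict]:
    from rdkit import Chem

    rows = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("skipping SDF entry %d: unreadable molecule", i)
            continue
        props = mol.GetPropsAsDict()
        rows.append(
            {
                "id": (mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"),
                "smiles": Chem.MolToSmiles(mol),
                "ld50": float(props[ld50_tag]) if ld50_tag in props else None,
                "route": props.get("route"),
                "species": props.get("species"),
            }
        )
    return rows


def write_labeled_csv(dataset: LabeledDataset, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "id": [r.id for r in dataset.records],
            "smiles": [r.smiles for r in dataset.records],
            "ld50": [r.ld50 for r in dataset.records],
            "route": [r.route for r in dataset.records],
            "species": [r.species for r in dataset.records],
            "label": dataset.labels,
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Labeling and filtering


def label_binary(records: Sequence[ChemicalRecord], cutoff: float) -> LabeledDataset:
    """Toxic (1) iff LD50 < cutoff mg/kg; LD50 == cutoff is nontoxic (0)."""
    if not cutoff > 0:
        raise ValueError("cutoff must be positive (mg/kg)")
    _require_ld50(records)
    scheme = LabelScheme(kind="binary", cutoff=float(cutoff),
                         class_names=("nontoxic", "toxic"))
    labels = np.array([scheme.assign(r.ld50) for r in records])
    return LabeledDataset(records=tuple(records), labels=labels, scheme=scheme)


DEFAULT_BOUNDARIES = (50.0, 500.0, 1000.0)


def label_multiclass(
    records: Sequence[ChemicalRecord],
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
) -> LabeledDataset:
    """Four-category dose-range labels over half-open LD50 intervals.

    With the default boundaries (50, 500, 1000) mg/kg the classes are
    [0,50) < [50,500) < [500,1000) < [1000, inf), ordered from most to
    least toxic.
    """
    bounds = tuple(float(b) for b in boundaries)
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("boundaries must be strictly increasing")
    _require_ld50(records)
    edges = ["0"] + [f"{b:g}" for b in bounds]
    names = tuple(
        f"[{lo},{hi})" for lo, hi in zip(edges, edges[1:])
    ) + (f"[{bounds[-1]:g},inf)",)
    scheme = LabelScheme(kind="categorical", boundaries=bounds, class_names=names)
    labels = np.array([scheme.assign(r.ld50) for r in records])
    logger.info("multiclass counts: %s", dict(zip(names, np.bincount(labels, minlength=len(names)))))
    return LabeledDataset(records=tuple(records), labels=labels, scheme=scheme)


def _require_ld50(records: Sequence[ChemicalRecord]) -> None:
    missing = [r.id for r in records if r.ld50 is None]
    if missing:
        raise ValueError(f"records missing LD50: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))


def filter_records(
    records: Iterable[ChemicalRecord],
    route: set[str] | None = None,
    species: set[str] | None = None,
) -> list[ChemicalRecord]:
    """Keep records matching all provided filters; order preserved."""
    routes = {normalize_route(r) for r in route} if route is not None else None
    specs = {s.strip().lower() for s in species} if species is not None else None
    out = []
    for rec in records:
        if routes is not None and rec.route not in routes:
            continue
        if specs is not None and (rec.species is None or rec.species.strip().lower() not in specs):
            continue
        out.append(rec)
    if not out:
        logger.warning("filter_records produced an empty result")
    return out


# ---------------------------------------------------------------------------
# Splitting and oversampling


def random_split(
    dataset: LabeledDataset,
    test_size: float | int,
    seed: int,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Disjoint, exhaustive random train/test partition.

    ``test_size`` may be a fraction in (0, 1) or an absolute count.  The
    protocol supports both the 20%-fraction and fixed-count test sets.
    """
    n = len(dataset)
    if isinstance(test_size, float) and 0 < test_size < 1:
        n_test = int(round(n * test_size))
    else:
        n_test = int(test_size)
    if not 0 < n_test < n:
        raise ValueError(f"test_size {test_size!r} out of range for n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    return dataset.subset(np.sort(perm[n_test:])), dataset.subset(np.sort(perm[:n_test]))


def oversample(
    train: LabeledDataset,
    targets: Mapping[int, int],
    seed: int,
) -> LabeledDataset:
    """Random oversampling with replacement up to per-class target counts.

    Every added row is an exact duplicate of an existing training row of
    that class; untargeted classes are untouched.
    """
    rng = np.random.default_rng(seed)
    counts = train.class_counts()
    extra: list[int] = []
    for cls, target in sorted(targets.items()):
        current = counts.get(cls, 0)
        if current == 0:
            raise ValueError(f"class {cls} absent from training set")
        if target < current:
            raise ValueError(
                f"class {cls}: target {target} below current count {current}"
            )
        pool = np.flatnonzero(train.labels == cls)
        extra.extend(rng.choice(pool, size=target - current, replace=True).tolist())
    keep = np.arange(len(train))
    idx = np.concatenate([keep, np.asarray(extra, dtype=np.int64)]) if extra else keep
    return train.subset(idx)
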