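"""Synthetic chemical datasets with a planted structure–toxicity signal.

The generator emits SMILES from a tiny valid-by-construction grammar
(linear carbon/oxygen/nitrogen chains with occasional branches and
double bonds), optionally carrying a toxicity motif — by default a
terminal nitrile group ``C#N``.  log10(LD50) is normal with a mean shift
for motif carriers (negative shift = more toxic), which makes the
planted effect analytically checkable, and a descriptor block encodes
the motif with tunable strength plus pure-noise columns.  Every emitted
string is guaranteed to parse in RDKit and to round-trip through the
one-hot codec, so fixtures never depend on a chemistry backend's
tolerance for edge cases.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
import json
from pathlib import Path

import numpy as np

from .data import ChemicalRecord, LabeledDataset, label_binary

__all__ = ["GeneratorConfig", "generate_dataset", "generate_imbalanced"]

# Descriptor block layout: columns 0..5 carry the motif signal with unit
# weight and noise sd 0.5; columns 6..9 are pure standard-normal noise.
_N_SIGNAL_COLS = 6
_N_NOISE_COLS = 4
_SIGNAL_NOISE_SD = 0.5


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    ``motif_effect`` is the additive shift in log10 LD50 (mg/kg) for
    motif carriers; the default -1.0 with sd 0.30 plants a strong,
    near-separable association (a motif-oracle classifier reaches AUC
    ~0.95 when classes are split at the mixture median).
    """

    n: int = 1000
    motif: str = "C#N"
    motif_prevalence: float = 0.5
    log_ld50_mean: float = 2.5
    log_ld50_sd: float = 0.30
    motif_effect: float = -1.0
    descriptor_signal: float = 1.0
    max_length: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.motif_prevalence <= 1.0:
            raise ValueError("motif_prevalence must lie in [0, 1]")
        if self.log_ld50_sd <= 0:
            raise ValueError("log_ld50_sd must be positive")
        if self.max_length < 20:
            raise ValueError("max_length must be >= 20 to fit the grammar")

    @property
    def n_descriptors(self) -> int:
        return _N_SIGNAL_COLS + _N_NOISE_COLS

    def median_ld50(self) -> float:
        """Median LD50 (mg/kg) of the generated mixture.

        With prevalence 0.5 the two-component normal mixture in log10
        dose is symmetric about mean + effect/2, so the median is exact;
        for other prevalences it is solved numerically.
        """
        from scipy.optimize import brentq
        from scipy.stats import norm

        p = self.motif_prevalence
        mu0, mu1 = self.log_ld50_mean, self.log_ld50_mean + self.motif_effect
        sd = self.log_ld50_sd
        if self.motif_effect == 0 or p in (0.0, 1.0):
            return float(10 ** (mu0 + p * self.motif_effect))
        if p == 0.5:
            return float(10 ** ((mu0 + mu1) / 2))
        cdf = lambda x: (1 - p) * norm.cdf(x, mu0, sd) + p * norm.cdf(x, mu1, sd) - 0.5
        lo, hi = min(mu0, mu1) - 6 * sd, max(mu0, mu1) + 6 * sd
        return float(10 ** brentq(cdf, lo, hi))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        return cls(**json.loads(Path(path).read_text()))


def _random_backbone(rng: np.random.Generator, budget: int) -> str:
    """A valence-safe linear SMILES: C/O/N chain, C-only branches and C=C.

    Heteroatoms and multiple bonds are only attached to carbons that have
    spare valence by construction, so every string is chemically valid.
    """
    n_heavy = int(rng.integers(4, 11))
    tokens = ["C"]
    prev_is_carbon = True
    prev_bond_multiple = False
    prev_branches = 0  # a chain carbon holds at most 2 branches (valence 4)
    for _ in range(n_heavy - 1):
        r = rng.random()
        if r < 0.15 and prev_is_carbon and not prev_bond_multiple and prev_branches == 0:
            tokens.append("=C")  # C=C unit; both carbons keep spare valence
            prev_is_carbon, prev_bond_multiple = True, True
            continue
        if r < 0.30 and prev_is_carbon and not prev_bond_multiple and prev_branches < 2:
            tokens.append("(C)")  # methyl branch off a carbon
            prev_branches += 1
            continue
        atom = str(rng.choice(["C", "C", "C", "O", "N"]))
        tokens.append(atom)
        prev_is_carbon = atom == "C"
        prev_bond_multiple = False
        prev_branches = 0
    smiles = "".join(tokens)
    return smiles[:budget] if len(smiles) <= budget else _trim_valid(smiles, budget)


def _trim_valid(smiles: str, budget: int) -> str:
    """Truncate at a point that leaves brackets balanced and bonds closed."""
    s = smiles[:budget]
    while s and (s.count("(") != s.count(")") or s[-1] in "=#("):
        s = s[:-1]
    return s or "C"


def generate_dataset(config: GeneratorConfig) -> list[ChemicalRecord]:
    """Draw ``config.n`` chemicals with SMILES, LD50 and descriptors."""
    rng = np.random.default_rng(config.seed)
    motif_len = len(config.motif)
    records: list[ChemicalRecord] = []
    has_motif = rng.random(config.n) < config.motif_prevalence
    log_ld50 = (
        config.log_ld50_mean
        + config.motif_effect * has_motif.astype(float)
        + config.log_ld50_sd * rng.standard_normal(config.n)
    )
    # descriptor block: motif signal + noise (see layout note above)
    signal = config.descriptor_signal * has_motif.astype(float)
    desc = np.empty((config.n, config.n_descriptors))
    desc[:, :_N_SIGNAL_COLS] = (
        signal[:, None] + _SIGNAL_NOISE_SD * rng.standard_normal((config.n, _N_SIGNAL_COLS))
    )
    desc[:, _N_SIGNAL_COLS:] = rng.standard_normal((config.n, _N_NOISE_COLS))

    for k in range(config.n):
        backbone = _random_backbone(rng, config.max_length - motif_len)
        smiles = backbone + config.motif if has_motif[k] else backbone
        records.append(
            ChemicalRecord(
                id=f"syn{k}",
                smiles=smiles,
                ld50=float(10 ** log_ld50[k]),
                route="oral",
                species="rat" if rng.random() < 0.5 else "mouse",
                descriptors=desc[k].copy(),
            )
        )
    return records


def generate_imbalanced(
    config: GeneratorConfig,
    cutoff: float,
    target_ratio: float,
    tolerance: float = 0.05,
    max_batches: int = 200,
) -> LabeledDataset:
    """Binary dataset whose nontoxic:toxic ratio matches ``target_ratio``.

    Rejection-samples from :func:`generate_dataset` until the requested
    class counts (within ``tolerance`` relative error on the ratio) are
    reached; labeling is delegated to :func:`smitox.data.label_binary`.
    """
    if target_ratio < 1:
        raise ValueError("target_ratio is nontoxic:toxic and must be >= 1")
    n_toxic = max(1, int(round(config.n / (1 + target_ratio))))
    n_nontoxic = config.n - n_toxic
    toxic_pool: list[ChemicalRecord] = []
    nontoxic_pool: list[ChemicalRecord] = []
    for batch in range(max_batches):
        batch_cfg = GeneratorConfig(**{**asdict(config), "seed": config.seed + 7919 * batch})
        for rec in generate_dataset(batch_cfg):
            rec = replace(rec, id=f"b{batch}_{rec.id}")
            if rec.ld50 < cutoff and len(toxic_pool) < n_toxic:
                toxic_pool.append(rec)
            elif rec.ld50 >= cutoff and len(nontoxic_pool) < n_nontoxic:
                nontoxic_pool.append(rec)
        if len(toxic_pool) >= n_toxic and len(nontoxic_pool) >= n_nontoxic:
            break
    else:
        raise RuntimeError(
            f"could not reach ratio {target_ratio}:1 at cutoff {cutoff} mg/kg "
            f"within {max_batches} sampling batches"
        )
    achieved = len(nontoxic_pool) / len(toxic_pool)
    if abs(achieved - target_ratio) / target_ratio > tolerance:
        raise RuntimeError(
            f"achieved ratio {achieved:.2f}:1 misses target {target_ratio}:1"
        )
    return label_binary(nontoxic_pool + toxic_pool, cutoff=cutoff)
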