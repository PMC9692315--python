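"""Tree-structured Parzen Estimator (TPE) hyperparameter search.

Sequential model-based optimization: after a random startup phase the
observed trials are split at the gamma quantile of the objective into a
"good" and a "bad" set, each numeric dimension is modelled with a Parzen
(Gaussian-mixture) density over each set, and the next point maximizes
the good/bad density ratio among sampled candidates.  The objective here
is ``1 - validation AUC`` so the best-ranking configuration wins.

The sampler is deliberately compact — independent one-dimensional
Parzen models with a spread-based bandwidth heuristic — which is all
that a search over a handful of architecture/training knobs needs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import replace
from typing import Callable, Mapping

import numpy as np

from .model import HybridConfig, HybridNetwork

logger = logging.getLogger(__name__)

__all__ = ["tpe_minimize", "tune_hyperparameters", "sample_params"]


def _check_space(space: Mapping[str, dict]) -> None:
    if not space:
        raise ValueError("search space must not be empty")
    for name, spec in space.items():
        kind = spec.get("type")
        if kind in ("uniform", "loguniform", "quniform"):
            if not spec["low"] < spec["high"]:
                raise ValueError(f"{name}: low must be < high")
            if kind == "loguniform" and spec["low"] <= 0:
                raise ValueError(f"{name}: loguniform needs positive bounds")
        elif kind == "choice":
            if not spec.get("options"):
                raise ValueError(f"{name}: choice needs non-empty options")
        else:
            raise ValueError(f"{name}: unknown distribution type {kind!r}")


def _to_internal(value: float, spec: dict) -> float:
    return math.log(value) if spec["type"] == "loguniform" else float(value)


def _from_internal(x: float, spec: dict):
    kind = spec["type"]
    lo, hi = spec["low"], spec["high"]
    if kind == "loguniform":
        return float(np.clip(math.exp(x), lo, hi))
    if kind == "quniform":
        q = spec.get("q", 1)
        return float(np.clip(round(x / q) * q, lo, hi))
    return float(np.clip(x, lo, hi))


def _bounds_internal(spec: dict) -> tuple[float, float]:
    if spec["type"] == "loguniform":
        return math.log(spec["low"]), math.log(spec["high"])
    return float(spec["low"]), float(spec["high"])


def sample_params(space: Mapping[str, dict], rng: np.random.Generator) -> dict:
    """Draw one configuration uniformly from the declared space."""
    out = {}
    for name, spec in space.items():
        if spec["type"] == "choice":
            out[name] = spec["options"][rng.integers(len(spec["options"]))]
        else:
            lo, hi = _bounds_internal(spec)
            out[name] = _from_internal(rng.uniform(lo, hi), spec)
    return out


def _parzen_logpdf(x: float, obs: np.ndarray, lo: float, hi: float) -> float:
    """Mixture of Gaussians centred on observations, plus a uniform prior
    component so the density never vanishes inside the bounds."""
    width = hi - lo
    bandwidth = max(width / max(len(obs), 1) ** 0.5, 1e-6 * width, 1e-12)
    z = (x - obs) / bandwidth
    comp = np.exp(-0.5 * z * z) / (bandwidth * math.sqrt(2 * math.pi))
    dens = 0.9 * comp.mean() + 0.1 / width
    return math.log(dens)


def _suggest(space, trials, rng, gamma: float, n_candidates: int) -> dict:
    losses = np.array([t["loss"] for t in trials])
    n_good = max(1, int(math.ceil(gamma * len(trials))))
    order = np.argsort(losses, kind="stable")
    good = [trials[i]["params"] for i in order[:n_good]]
    bad = [trials[i]["params"] for i in order[n_good:]] or good

    out = {}
    for name, spec in space.items():
        if spec["type"] == "choice":
            options = spec["options"]
            counts_g = np.array(
                [sum(1 for p in good if p[name] == o) for o in options], float)
            counts_b = np.array(
                [sum(1 for p in bad if p[name] == o) for o in options], float)
            pg = (counts_g + 1) / (counts_g.sum() + len(options))
            pb = (counts_b + 1) / (counts_b.sum() + len(options))
            out[name] = options[int(np.argmax(pg / pb))]
            continue
        lo, hi = _bounds_internal(spec)
        obs_g = np.array([_to_internal(p[name], spec) for p in good])
        obs_b = np.array([_to_internal(p[name], spec) for p in bad])
        centers = obs_g[rng.integers(len(obs_g), size=n_candidates)]
        bandwidth = max((hi - lo) / max(len(obs_g), 1) ** 0.5, 1e-12)
        cands = np.clip(centers + bandwidth * rng.standard_normal(n_candidates),
                        lo, hi)
        scores = [
            _parzen_logpdf(c, obs_g, lo, hi) - _parzen_logpdf(c, obs_b, lo, hi)
            for c in cands
        ]
        out[name] = _from_internal(float(cands[int(np.argmax(scores))]), spec)
    return out


def tpe_minimize(
    objective: Callable[[dict], float],
    space: Mapping[str, dict],
    n_trials: int,
    seed: int = 0,
    n_startup: int = 10,
    gamma: float = 0.25,
    n_candidates: int = 24,
) -> tuple[dict, list[dict]]:
    """Minimize ``objective`` over ``space``; returns (best_params, trial log).

    Every trial is logged as ``{"params", "loss"}`` (``loss`` is ``inf``
    for trials whose objective raised); the returned parameters are the
    argmin over successful trials.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    _check_space(space)
    rng = np.random.default_rng(seed)
    trials: list[dict] = []
    for i in range(n_trials):
        ok = [t for t in trials if math.isfinite(t["loss"])]
        if i < n_startup or len(ok) < 2:
            params = sample_params(space, rng)
        else:
            params = _suggest(space, ok, rng, gamma, n_candidates)
        try:
            loss = float(objective(params))
        except Exception as exc:
            logger.warning("trial %d failed: %s", i, exc)
            loss = float("inf")
        trials.append({"params": params, "loss": loss})
    finite = [t for t in trials if math.isfinite(t["loss"])]
    if not finite:
        raise RuntimeError("all TPE trials failed")
    best = min(finite, key=lambda t: t["loss"])
    return best["params"], trials


# Keys that map onto a single-block convolution stack rather than a
# HybridConfig field directly.
_CONV_KEYS = ("n_filters", "kernel_length", "pool_length")


def config_from_params(params: Mapping[str, object],
                       base: HybridConfig) -> HybridConfig:
    """Overlay sampled parameters onto a base configuration."""
    overrides = {k: v for k, v in params.items() if k not in _CONV_KEYS}
    for key in ("epochs", "batch_size", "patience"):
        if key in overrides:
            overrides[key] = int(overrides[key])
    if "ffnn_hidden" in overrides:
        overrides["ffnn_hidden"] = tuple(overrides["ffnn_hidden"])
    cfg = replace(base, **overrides)
    if any(k in params for k in _CONV_KEYS):
        f0, k0, p0 = base.conv_blocks[0]
        block = (int(params.get("n_filters", f0)),
                 int(params.get("kernel_length", k0)),
                 int(params.get("pool_length", p0)))
        cfg = replace(cfg, conv_blocks=(block,))
    return cfg


def tune_hyperparameters(
    search_space: Mapping[str, dict],
    train: tuple,
    validation: tuple,
    n_trials: int,
    seed: int = 0,
    base_config: HybridConfig | None = None,
) -> tuple[HybridConfig, list[dict]]:
    """TPE search over hybrid-network hyperparameters.

    ``train`` and ``validation`` are ``(smiles_tensor, descriptors,
    labels)`` triples; each trial trains a hybrid network on the training
    triple and is scored by ``1 - AUC`` on the validation triple.
    Returns the best configuration and the full trial log.
    """
    base = base_config or HybridConfig()
    s_tr, d_tr, y_tr = train
    s_va, d_va, y_va = validation
    y_tr = np.asarray(y_tr)
    n_classes = int(max(y_tr.max(), np.asarray(y_va).max())) + 1

    def objective(params: dict) -> float:
        cfg = config_from_params(params, replace(base, seed=seed))
        x = s_tr.data if hasattr(s_tr, "data") else np.asarray(s_tr)
        d = d_tr.values if hasattr(d_tr, "values") else np.asarray(d_tr)
        net = HybridNetwork(cfg, x.shape[1], x.shape[2], d.shape[1],
                            n_classes=n_classes)
        net.fit(s_tr, d_tr, y_tr, validation=(s_va, d_va, y_va))
        return 1.0 - net._auc(np.asarray(y_va), net.predict_proba(s_va, d_va))

    best_params, trials = tpe_minimize(objective, search_space, n_trials, seed)
    return config_from_params(best_params, base), trials
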