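"""Hyper-parameter search, top-k selection and soft-voting aggregation.

The final predictor averages the probability vectors of the top three
base classifiers ranked by held-out validation accuracy (soft voting).
Hard majority voting is available behind a flag.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .model import (
    BaseClassifier,
    BaseClassifierSpec,
    TrainingLog,
    _stratified_holdout,
    build_base_classifier,
    load_checkpoint,
    save_checkpoint,
    train_base_classifier,
)

logger = logging.getLogger(__name__)


@dataclass
class Candidate:
    spec: BaseClassifierSpec
    model: BaseClassifier
    validation_acc: float
    grid_index: int
    log: TrainingLog | None = None


def default_grid(base: BaseClassifierSpec | None = None, limit: int = 12) -> list[BaseClassifierSpec]:
    """Grid varying conv filters, LSTM width, heads and dropout around the
    defaults, truncated to `limit` specs for desk-scale runtime."""
    base = base or BaseClassifierSpec()
    specs = []
    for filters, hidden, heads, drop in itertools.product(
        (32, 64), (32, 64), (2, 4), (0.3, 0.5)
    ):
        specs.append(replace(
            base,
            conv1_filters=filters, conv2_filters=filters,
            lstm_hidden=hidden, attention_heads=heads,
            dropout_rates=(drop, drop),
        ))
    return specs[:limit]


def hyperparameter_search(
    grid: list[BaseClassifierSpec],
    X: np.ndarray,
    y: np.ndarray,
    val_fraction: float = 0.1,
    seed: int = 0,
) -> list[Candidate]:
    """Train every spec on a shared stratified train/validation split and
    return candidates sorted by validation accuracy, descending (stable:
    ties keep grid order).  Individual training failures are logged and
    skipped; an error is raised only if every spec fails."""
    if not grid:
        raise ValueError("empty hyper-parameter grid")
    tr_idx, va_idx = _stratified_holdout(np.asarray(y), val_fraction, seed)
    pool: list[Candidate] = []
    for i, spec in enumerate(grid):
        try:
            model = build_base_classifier(spec, X.shape[1:])
            model, log = train_base_classifier(
                model, (X[tr_idx], y[tr_idx]), (X[va_idx], y[va_idx])
            )
            pool.append(Candidate(spec=spec, model=model,
                                  validation_acc=model.validation_acc,
                                  grid_index=i, log=log))
        except Exception as exc:
            logger.warning("grid member %d failed: %s", i, exc)
    if not pool:
        raise RuntimeError("all grid members failed to train")
    pool.sort(key=lambda c: (-c.validation_acc, c.grid_index))
    return pool


class EnsembleModel:
    """Fixed-size collection of trained base classifiers with probability
    averaging (default) or hard majority voting."""

    def __init__(self, members: list[BaseClassifier], member_accs: list[float] | None = None,
                 voting: str = "soft", threshold: float = 0.5):
        if not members:
            raise ValueError("ensemble needs at least one member")
        if voting not in ("soft", "hard"):
            raise ValueError("voting must be 'soft' or 'hard'")
        self.members = list(members)
        self.member_accs = list(member_accs) if member_accs is not None else [
            m.validation_acc for m in members
        ]
        self.voting = voting
        self.threshold = threshold

    def __len__(self) -> int:
        return len(self.members)

    def member_probas(self, X: np.ndarray) -> np.ndarray:
        """(k, n, 2) stack of member probability outputs."""
        return np.stack([m.predict_proba(X) for m in self.members])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.member_probas(X).mean(axis=0)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(probabilities, hard labels); label 1 iff mean p_positive >= threshold."""
        probs = self.member_probas(X)
        mean = probs.mean(axis=0)
        if self.voting == "soft":
            labels = (mean[:, 1] >= self.threshold).astype(int)
        else:
            votes = (probs[:, :, 1] >= self.threshold).sum(axis=0)
            labels = (votes * 2 >= len(self.members)).astype(int)
        return mean, labels


def select_top_k(pool: list[Candidate], k: int = 3, voting: str = "soft") -> EnsembleModel:
    """The k highest-accuracy candidates; ties keep earlier grid order."""
    if len(pool) < k:
        raise ValueError(
            f"pool has {len(pool)} candidates but k={k}; train a larger grid "
            "or request a smaller k"
        )
    chosen = sorted(pool, key=lambda c: (-c.validation_acc, c.grid_index))[:k]
    return EnsembleModel(
        members=[c.model for c in chosen],
        member_accs=[c.validation_acc for c in chosen],
        voting=voting,
    )


def ensemble_predict(model: EnsembleModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return model.predict(X)


# ---------------------------------------------------------------------------
# checkpointing: directory of member checkpoints + manifest


def save_ensemble(model: EnsembleModel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for i, member in enumerate(model.members):
        name = f"member_{i}"
        save_checkpoint(member, directory / name)
        names.append(name)
    manifest = {
        "members": names,
        "member_accs": model.member_accs,
        "aggregation": model.voting,
        "threshold": model.threshold,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_ensemble(directory) -> EnsembleModel:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    members = [load_checkpoint(directory / name) for name in manifest["members"]]
    return EnsembleModel(
        members=members,
        member_accs=manifest.get("member_accs"),
        voting=manifest.get("aggregation", "soft"),
        threshold=manifest.get("threshold", 0.5),
    )
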