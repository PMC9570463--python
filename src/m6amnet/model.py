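"""One base classifier: a multi-head self-attention front-end feeding two
parallel branches — a two-layer CNN with max pooling, and a BiLSTM whose
final states pass through a ReLU fully connected layer — concatenated into
a two-layer prediction head with dropout and a 2-class softmax output.

Ablation flags remove components: ``no_attention`` feeds raw encodings to
the branches, ``cnn_only`` / ``bilstm_only`` drop the other branch.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import nn
from .encoding import DEFAULT_SCHEME, FeatureScheme, encode_batch

_ABLATIONS = {"no_attention", "cnn_only", "bilstm_only"}


@dataclass(frozen=True)
class BaseClassifierSpec:
    attention_heads: int = 4
    attention_model_dim: int = 64
    conv1_filters: int = 64
    conv1_kernel: int = 5
    conv2_filters: int = 64
    conv2_kernel: int = 3
    pool_size: int = 2
    lstm_hidden: int = 64
    branch_fc_dim: int = 64
    head_fc_dims: tuple[int, int] = (64, 2)
    dropout_rates: tuple[float, float] = (0.5, 0.5)
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    ablation: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "ablation", frozenset(self.ablation))
        unknown = self.ablation - _ABLATIONS
        if unknown:
            raise ValueError(f"unknown ablation flag(s): {sorted(unknown)}")
        if {"cnn_only", "bilstm_only"} <= self.ablation:
            raise ValueError("cannot ablate both branches")
        if self.attention_model_dim % self.attention_heads:
            raise ValueError("attention_model_dim must be divisible by attention_heads")
        for name in ("attention_heads", "attention_model_dim", "conv1_filters",
                     "conv2_filters", "pool_size", "lstm_hidden", "branch_fc_dim",
                     "batch_size", "max_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not all(0.0 <= d < 1.0 for d in self.dropout_rates):
            raise ValueError("dropout rates must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    @property
    def use_attention(self) -> bool:
        return "no_attention" not in self.ablation

    @property
    def use_cnn(self) -> bool:
        return "bilstm_only" not in self.ablation

    @property
    def use_bilstm(self) -> bool:
        return "cnn_only" not in self.ablation

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["ablation"] = sorted(d["ablation"])
        d["head_fc_dims"] = list(d["head_fc_dims"])
        d["dropout_rates"] = list(d["dropout_rates"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BaseClassifierSpec":
        d = dict(d)
        d["ablation"] = frozenset(d.get("ablation", ()))
        d["head_fc_dims"] = tuple(d.get("head_fc_dims", (64, 2)))
        d["dropout_rates"] = tuple(d.get("dropout_rates", (0.5, 0.5)))
        return cls(**d)


@dataclass
class TrainingLog:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1
    wall_seconds: float = 0.0

    def loss_trajectory(self) -> list[float]:
        return [e["train_loss"] for e in self.epochs]


class BaseClassifier:
    """Topology + weights; built untrained, fitted by `train_base_classifier`."""

    def __init__(self, spec: BaseClassifierSpec, input_shape: tuple[int, int] = (41, 8),
                 dtype=np.float32):
        self.spec = spec
        self.input_shape = tuple(input_shape)
        self.validation_acc: float | None = None
        self.trained = False
        length, channels = self.input_shape
        for k in (spec.conv1_kernel, spec.conv2_kernel):
            if k > length:
                raise ValueError(f"kernel size {k} exceeds window length {length}")
        rng = np.random.default_rng(spec.seed)

        branch_in = spec.attention_model_dim if spec.use_attention else channels
        self.attention = (
            nn.MultiHeadSelfAttention(channels, spec.attention_model_dim,
                                      spec.attention_heads, rng, dtype)
            if spec.use_attention else None
        )
        head_in = 0
        self.conv1 = self.conv2 = None
        if spec.use_cnn:
            self.conv1 = nn.Conv1d(branch_in, spec.conv1_filters, spec.conv1_kernel, rng, dtype)
            self.conv2 = nn.Conv1d(spec.conv1_filters, spec.conv2_filters, spec.conv2_kernel, rng, dtype)
            post_conv = length - spec.conv1_kernel - spec.conv2_kernel + 2
            pooled = post_conv // spec.pool_size
            if pooled < 1:
                raise ValueError(
                    f"pool size {spec.pool_size} larger than post-conv length {post_conv}"
                )
            head_in += pooled * spec.conv2_filters
        self.lstm = self.branch_fc = None
        if spec.use_bilstm:
            self.lstm = nn.BiLSTM(branch_in, spec.lstm_hidden, rng, dtype)
            self.branch_fc = nn.Dense(2 * spec.lstm_hidden, spec.branch_fc_dim, rng, dtype)
            head_in += spec.branch_fc_dim
        self.fc1 = nn.Dense(head_in, spec.head_fc_dims[0], rng, dtype)
        self.fc2 = nn.Dense(spec.head_fc_dims[0], spec.head_fc_dims[1], rng, dtype)

    # -- parameters -------------------------------------------------------

    def parameters(self) -> list[nn.Tensor]:
        params = []
        for layer in (self.attention, self.conv1, self.conv2, self.lstm,
                      self.branch_fc, self.fc1, self.fc2):
            if layer is not None:
                params.extend(layer.params())
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights, strict=True):
            p.data = w.copy()

    # -- forward ----------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> nn.Tensor:
        t = nn.Tensor(x.astype(np.float32, copy=False))
        h = self.attention(t) if self.attention is not None else t
        feats = []
        if self.conv1 is not None:
            c = self.conv1(h).relu()
            c = self.conv2(c).relu()
            c = nn.maxpool1d(c, self.spec.pool_size)
            b = c.shape[0]
            feats.append(c.reshape(b, -1))
        if self.lstm is not None:
            s = self.lstm(h)
            feats.append(self.branch_fc(s).relu())
        z = nn.cat(feats, axis=1) if len(feats) > 1 else feats[0]
        z = self.fc1(z).relu()
        if train:
            z = nn.dropout(z, self.spec.dropout_rates[0], rng)
        z = self.fc2(z)
        if train:
            z = nn.dropout(z, self.spec.dropout_rates[1], rng)
        return z

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Per-window (p_negative, p_positive); rows sum to 1."""
        if X.ndim != 3 or X.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected encoded input of shape (n, {self.input_shape[0]}, "
                f"{self.input_shape[1]}), got {X.shape}"
            )
        chunks = []
        for start in range(0, len(X), batch_size):
            logits = self.forward(X[start : start + batch_size], train=False)
            chunks.append(nn.softmax_probs(logits.data))
        return np.concatenate(chunks, axis=0)

    def predict_proba_sequences(self, windows: list[str],
                                scheme: FeatureScheme = DEFAULT_SCHEME) -> np.ndarray:
        for i, w in enumerate(windows):
            if len(w) != self.input_shape[0]:
                raise ValueError(
                    f"record {i} has length {len(w)}, expected {self.input_shape[0]}"
                )
        return self.predict_proba(encode_batch(windows, scheme))


def build_base_classifier(spec: BaseClassifierSpec,
                          input_shape: tuple[int, int] = (41, 8)) -> BaseClassifier:
    return BaseClassifier(spec, input_shape)


def train_base_classifier(
    model: BaseClassifier,
    train: tuple[np.ndarray, np.ndarray],
    valid: tuple[np.ndarray, np.ndarray],
) -> tuple[BaseClassifier, TrainingLog]:
    """Cross-entropy training with Adam and early stopping on validation
    accuracy; the best-epoch weights are restored before returning.

    Deterministic for a fixed spec seed: initialization, shuffling and
    dropout all draw from generators derived from ``spec.seed``.
    """
    X, y = train
    Xv, yv = valid
    if len(X) == 0 or len(Xv) == 0:
        raise ValueError("empty train or validation partition")
    spec = model.spec
    rng = np.random.default_rng(spec.seed + 1)
    opt = nn.Adam(model.parameters(), lr=spec.learning_rate)
    log = TrainingLog()
    best_acc = -1.0
    best_weights = model.get_weights()
    bad_epochs = 0
    t0 = time.perf_counter()
    for epoch in range(spec.max_epochs):
        perm = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), spec.batch_size):
            idx = perm[start : start + spec.batch_size]
            logits = model.forward(X[idx], train=True, rng=rng)
            loss = nn.cross_entropy(logits, y[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)}; "
                    "try a lower learning rate"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_p = model.predict_proba(Xv)[:, 1]
        val_acc = float(((val_p >= 0.5).astype(int) == yv).mean())
        log.epochs.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                           "val_acc": val_acc})
        if val_acc > best_acc:
            best_acc = val_acc
            best_weights = model.get_weights()
            log.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= spec.patience:
                break
    log.stopped_epoch = log.epochs[-1]["epoch"]
    log.wall_seconds = time.perf_counter() - t0
    model.set_weights(best_weights)
    model.validation_acc = best_acc
    model.trained = True
    return model, log


def predict_proba(model: BaseClassifier, windows: list[str],
                  scheme: FeatureScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Module-level convenience wrapper over sequence prediction."""
    return model.predict_proba_sequences(windows, scheme)


# ---------------------------------------------------------------------------
# checkpoints

_FORMAT_VERSION = 1


def save_checkpoint(model: BaseClassifier, directory) -> None:
    """Self-describing checkpoint: weights npz + JSON spec sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(directory / "weights.npz", **arrays)
    meta = {
        "format_version": _FORMAT_VERSION,
        "spec": model.spec.to_dict(),
        "input_shape": list(model.input_shape),
        "validation_acc": model.validation_acc,
        "trained": model.trained,
    }
    with open(directory / "spec.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_checkpoint(directory) -> BaseClassifier:
    directory = Path(directory)
    with open(directory / "spec.json") as fh:
        meta = json.load(fh)
    if meta.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported checkpoint format {meta.get('format_version')}")
    spec = BaseClassifierSpec.from_dict(meta["spec"])
    model = BaseClassifier(spec, tuple(meta["input_shape"]))
    with np.load(directory / "weights.npz") as npz:
        model.set_weights([npz[f"w{i}"] for i in range(len(npz.files))])
    model.validation_acc = meta.get("validation_acc")
    model.trained = bool(meta.get("trained"))
    return model


def make_recipe(spec: BaseClassifierSpec, input_shape: tuple[int, int] = (41, 8),
                val_fraction: float = 0.1):
    """Adapt a spec to the `recipe(X, y, seed)` protocol used by the
    evaluation module: carves a stratified validation split from the
    training partition for early stopping, then returns the fitted model."""

    def recipe(X, y, seed: int = 0):
        sp = replace(spec, seed=spec.seed + seed)
        model = build_base_classifier(sp, input_shape)
        tr_idx, va_idx = _stratified_holdout(y, val_fraction, sp.seed)
        model, _ = train_base_classifier(model, (X[tr_idx], y[tr_idx]), (X[va_idx], y[va_idx]))
        return model

    return recipe


def _stratified_holdout(y: np.ndarray, fraction: float, seed: int):
    """Indices for a (rest, held-out) stratified split of one label array."""
    rng = np.random.default_rng(seed)
    held = []
    rest = []
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        perm = rng.permutation(len(members))
        n_held = max(1, int(round(fraction * len(members))))
        held.extend(members[perm[:n_held]])
        rest.extend(members[perm[n_held:]])
    return np.sort(np.array(rest)), np.sort(np.array(held))
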